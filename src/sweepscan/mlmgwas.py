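"""Mixed-model association scan (single null variance-component fit),
genomic inflation, and effective-number-of-tests significance thresholds.

The model is y = X b + Zu g + e with g ~ N(0, sigma_g^2 K) and
e ~ N(0, sigma_e^2 I).  Variance components are estimated once by REML under
the null (no SNP term) through the spectral decomposition of the kinship
matrix restricted to the covariate-orthogonal subspace; every SNP is then
tested by generalized least squares after whitening with the fitted V^{-1/2}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genodata import MISSING, GenotypeMatrix
from .selscan import CHI2_MEDIAN_1DF, standardized_dosage


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    delta: float  # sigma_e2 / sigma_g2
    loglik: float
    h2: float


@dataclass
class AssocResult:
    """Per-SNP mixed-model scan output for one trait."""

    table: pd.DataFrame  # chrom, pos, beta, se, chisq, p
    lambda_gc: float
    vc: VarianceComponents
    me: float | None = None
    thresholds: tuple | None = None  # (suggestive, significant)
    meta: dict = field(default_factory=dict)


def kinship_matrix(gm: GenotypeMatrix) -> np.ndarray:
    """Genomic relationship matrix K = Z Z' / m from standardized, mean-imputed
    dosages (mean diagonal ~ 1 for an outbred cohort)."""
    Z, poly = standardized_dosage(gm)
    m = int(poly.sum())
    if m == 0:
        raise ValueError("no polymorphic SNP for kinship")
    return Z @ Z.T / m


def _reml_loglik(delta: float, lam: np.ndarray, eta2: np.ndarray) -> float:
    nq = lam.size
    denom = lam + delta
    s = float(np.sum(eta2 / denom))
    if s <= 0 or not np.isfinite(s):
        return -np.inf
    return 0.5 * (
        nq * (np.log(nq / (2 * np.pi)) - 1.0 - np.log(s)) - float(np.sum(np.log(denom)))
    )


def reml_fit(
    y: np.ndarray,
    covariates: np.ndarray | None,
    K: np.ndarray,
    grid_points: int = 100,
) -> VarianceComponents:
    """REML estimate of (sigma_g^2, sigma_e^2) via a log-spaced grid over
    delta = sigma_e^2/sigma_g^2 in [1e-5, 1e5] followed by bounded scalar
    refinement.

    ``covariates`` excludes the intercept (added internally); samples with a
    missing phenotype must be dropped by the caller.
    """
    y = np.asarray(y, float)
    n = y.size
    X = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates]
    )
    q = X.shape[1]
    if np.linalg.matrix_rank(X) < q:
        raise ValueError("covariate matrix is rank deficient")
    # restricted spectral decomposition: eigenpairs of S K S, S the projector
    # onto the orthogonal complement of the covariates
    S = np.eye(n) - X @ np.linalg.solve(X.T @ X, X.T)
    vals, vecs = np.linalg.eigh(S @ K @ S)
    order = np.argsort(vals)[::-1][: n - q]
    lam = np.maximum(vals[order], 0.0)
    U = vecs[:, order]
    eta2 = (U.T @ y) ** 2
    if np.ptp(lam) < 1e-10:
        import warnings

        warnings.warn(
            "kinship is (near) identity on the restricted subspace: "
            "delta is not identifiable",
            stacklevel=2,
        )
    grid = np.logspace(-5, 5, grid_points)
    ll = np.array([_reml_loglik(d, lam, eta2) for d in grid])
    if not np.isfinite(ll).any():
        raise ValueError("REML likelihood non-finite across the whole grid")
    best = int(np.argmax(ll))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid_points - 1)]
    # refine in log-delta for scale invariance
    res = optimize.minimize_scalar(
        lambda t: -_reml_loglik(np.exp(t), lam, eta2),
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    delta = float(np.exp(res.x))
    sigma_g2 = float(np.sum(eta2 / (lam + delta)) / (n - q))
    sigma_e2 = delta * sigma_g2
    return VarianceComponents(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        delta=delta,
        loglik=_reml_loglik(delta, lam, eta2),
        h2=sigma_g2 / (sigma_g2 + sigma_e2),
    )


def mlm_scan(
    gm: GenotypeMatrix,
    y: np.ndarray,
    covariates: np.ndarray | None,
    K: np.ndarray,
    vc: VarianceComponents | None = None,
) -> AssocResult:
    """Whitened generalized-least-squares scan of every SNP.

    ``vc`` is fitted under the null when not supplied.  SNPs collinear with
    the covariates (zero residual dosage variance) get missing P.
    """
    y = np.asarray(y, float)
    n = y.size
    if vc is None:
        vc = reml_fit(y, covariates, K)
    vals, vecs = np.linalg.eigh(K)
    vals = np.maximum(vals, 0.0)
    w = 1.0 / np.sqrt(vc.sigma_g2 * vals + vc.sigma_e2)
    W = vecs @ (w[:, None] * vecs.T)  # V^{-1/2}
    X = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates]
    )
    q = X.shape[1]
    ys = W @ y
    Xs = W @ X
    d = gm.dosage.astype(float)
    d[gm.dosage == MISSING] = np.nan
    d = np.where(np.isnan(d), np.nanmean(d, axis=0)[None, :], d)
    Gs = W @ d
    # project out the whitened covariates (Frisch-Waugh)
    Q, _ = np.linalg.qr(Xs)
    yr = ys - Q @ (Q.T @ ys)
    Gr = Gs - Q @ (Q.T @ Gs)
    gtg = (Gr**2).sum(axis=0)
    ok = gtg > 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = (Gr * yr[:, None]).sum(axis=0) / gtg
        rss = np.maximum((yr**2).sum() - beta**2 * gtg, 0.0)
        se = np.sqrt(rss / (n - q - 1) / gtg)
        chisq = (beta / se) ** 2
    beta[~ok] = np.nan
    se[~ok] = np.nan
    chisq[~ok] = np.nan
    p = stats.chi2.sf(chisq, df=1)
    lam = float(np.nanmedian(chisq) / CHI2_MEDIAN_1DF)
    table = pd.DataFrame(
        {
            "chrom": gm.variants["chrom"],
            "pos": gm.variants["pos"],
            "beta": beta,
            "se": se,
            "chisq": chisq,
            "p": p,
        }
    )
    return AssocResult(table=table, lambda_gc=lam, vc=vc)


def effective_tests(gm: GenotypeMatrix, block_size_snps: int = 1000) -> float:
    """LD-adjusted effective number of independent tests.

    Within consecutive per-chromosome blocks, the eigenvalues lambda_i of the
    SNP-SNP dosage correlation matrix give a block contribution
    sum_i [ 1(lambda_i >= 1) + (lambda_i - floor(lambda_i)) ]; the genome
    total is the sum over blocks.  Monomorphic SNPs carry no test and are
    excluded.
    """
    if block_size_snps < 1:
        raise ValueError("block_size_snps must be >= 1")
    d = gm.dosage.astype(float)
    d[gm.dosage == MISSING] = np.nan
    mean = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), mean[None, :], d)
    sd = d.std(axis=0)
    chrom_arr = gm.variants["chrom"].to_numpy()
    me = 0.0
    for chrom in pd.unique(chrom_arr):
        idx = np.flatnonzero((chrom_arr == chrom) & (sd > 0))
        for s in range(0, idx.size, block_size_snps):
            block = idx[s : s + block_size_snps]
            if block.size == 1:
                me += 1.0
                continue
            corr = np.corrcoef(d[:, block].T)
            lam = np.linalg.eigvalsh(corr)
            lam = np.maximum(lam, 0.0)
            me += float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
    return me


def significance_thresholds(me: float) -> tuple[float, float]:
    """(suggestive, significant) genome-wide P cutoffs = (1/Me, 0.05/Me)."""
    if me < 1:
        raise ValueError("effective test count must be >= 1")
    return 1.0 / me, 0.05 / me
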