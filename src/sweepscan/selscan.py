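"""Three genome-wide selection scans and their consensus.

The scans contrast a wild reference group (PIM) against a cultivated object
group (BIG):

* ``pi_ratio_scan`` — windowed nucleotide diversity ratio pi_PIM / pi_BIG;
  diversity collapse in the cultivated group drives the ratio up.
* ``eigengwas_scan`` — association of each SNP with the first genotype PCA
  eigenvector, genomic-control corrected; differentiated loci load on PC1.
* ``xpclr_scan`` — cross-population composite likelihood ratio contrasting a
  Brownian-drift neutral model of allele-frequency change against a
  hitchhiking model in which the object-population frequency has either
  escaped (probability c, depending on recombination distance r and selection
  strength s) or been dragged to fixation.

Selection in every scan is by empirical top quantile; selected windows are
merged into regions when closer than a gap threshold, and a gene-level
bitmask supports the three-way consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genodata import (
    MISSING,
    GenomicRegion,
    GenotypeMatrix,
    GroupAssignment,
    WindowGrid,
    assign_genes,
)

CHI2_MEDIAN_1DF = 0.4549364231195724  # median of chi^2_1


@dataclass
class ScanResult:
    """Per-window outcome of one selection scan."""

    method: str
    table: pd.DataFrame  # chrom, start, end, stat, quantile, selected
    threshold: float
    meta: dict = field(default_factory=dict)

    def selected_windows(self) -> pd.DataFrame:
        return self.table[self.table["selected"]]

    def selected_regions(self, max_gap_bp: int = 100_000) -> list[GenomicRegion]:
        sel = self.selected_windows()
        regions = [
            GenomicRegion(r.chrom, int(r.start), int(r.end))
            for r in sel.itertuples()
        ]
        return merge_regions(regions, max_gap_bp)


@dataclass(frozen=True)
class DriftParam:
    """Genome-wide drift variance scaling between reference and object
    population allele frequencies (Var[p_obj - p_ref] = omega * p_ref(1-p_ref))."""

    omega: float

    def __post_init__(self):
        if self.omega < 0:
            raise ValueError("omega must be >= 0")


@dataclass(frozen=True)
class SweepModel:
    """Alternative (hitchhiking) model parameters for the composite
    likelihood scan: selection-strength grid and beneficial-allele starting
    frequency q0 (default 1/(2N) with N = 100).

    The grid includes a vanishingly small strength so that escape is certain
    (c ~ 1) for every SNP at positive distance, recovering the neutral model
    and keeping the likelihood ratio non-negative."""

    s_grid: tuple = (1e-12,) + tuple(np.logspace(-5, -1, 12))
    q0: float = 0.005

    def __post_init__(self):
        if not all(s > 0 for s in self.s_grid):
            raise ValueError("selection grid values must be > 0")
        if not 0 < self.q0 < 1:
            raise ValueError("q0 must be in (0, 1)")

    def escape_prob(self, r) -> np.ndarray:
        """c(r; s) = 1 - q0^(r/s) for every s in the grid; shape (n_s, n_r)."""
        r = np.atleast_1d(np.asarray(r, dtype=float))
        s = np.asarray(self.s_grid)[:, None]
        return 1.0 - np.power(self.q0, r[None, :] / s)


# ---------------------------------------------------------------------------
# windowed pi and the pi-ratio scan
# ---------------------------------------------------------------------------


def site_pi(gm: GenotypeMatrix, sample_idx: np.ndarray) -> np.ndarray:
    """Unbiased per-site nucleotide diversity 2a(n-a)/(n(n-1)) from allele
    counts among non-missing calls; 0 where < 2 alleles are called."""
    a, n = gm.alt_counts(sample_idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * a * (n - a) / (n * (n - 1.0))
    pi[n < 2] = 0.0
    return pi


def _window_sums(
    values: np.ndarray, gm: GenotypeMatrix, grid: WindowGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Sum of a per-site quantity and site counts per window (prefix sums)."""
    chrom_arr = gm.variants["chrom"].to_numpy()
    pos_arr = gm.variants["pos"].to_numpy()
    sums = np.zeros(len(grid))
    counts = np.zeros(len(grid), dtype=int)
    for chrom in pd.unique(grid.windows["chrom"]):
        vmask = chrom_arr == chrom
        pos = pos_arr[vmask]
        vals = values[vmask]
        cs = np.concatenate([[0.0], np.cumsum(vals)])
        wmask = grid.windows["chrom"].to_numpy() == chrom
        starts = grid.windows["start"].to_numpy()[wmask]
        ends = grid.windows["end"].to_numpy()[wmask]
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        sums[wmask] = cs[hi] - cs[lo]
        counts[wmask] = hi - lo
    return sums, counts


def windowed_pi(
    gm: GenotypeMatrix, group: str, groups: GroupAssignment, grid: WindowGrid
) -> np.ndarray:
    """Per-window pi: summed site diversity divided by window length in bp.

    Non-variant positions count as invariant (whole-genome resequencing
    assumption); a window with no callable SNP has pi = 0.
    """
    idx = groups.sample_idx(gm, group)
    pi = site_pi(gm, idx)
    sums, _ = _window_sums(pi, gm, grid)
    lengths = (grid.windows["end"] - grid.windows["start"]).to_numpy(float)
    return sums / lengths


def pi_ratio_scan(
    pi_ref: np.ndarray, pi_obj: np.ndarray, grid: WindowGrid, top: float = 0.05
) -> ScanResult:
    """Rank windows by pi_ref / pi_obj and select the empirical top fraction.

    Windows where the object group has pi = 0 but the reference does not get
    an infinite ratio and outrank every finite window; windows with both
    pi = 0 are excluded from ranking.
    """
    if len(pi_ref) != len(grid) or len(pi_obj) != len(grid):
        raise ValueError("pi vectors do not match the window grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pi_obj > 0, pi_ref / pi_obj, np.where(pi_ref > 0, np.inf, np.nan))
    return _rank_and_select(ratio, grid, "PDS_pi", top)


# ---------------------------------------------------------------------------
# EigenGWAS
# ---------------------------------------------------------------------------


def standardized_dosage(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean-imputed, (g - 2p)/sqrt(2p(1-p)) standardized dosage matrix.

    Returns ``(Z, polymorphic_mask)``; monomorphic columns are zeroed and
    flagged False.
    """
    d = gm.dosage.astype(float)
    d[gm.dosage == MISSING] = np.nan
    p = np.nanmean(d, axis=0) / 2.0
    mono = ~(np.nan_to_num(p) * (1 - np.nan_to_num(p)) > 0)
    col_mean = 2.0 * p
    d = np.where(np.isnan(d), col_mean[None, :], d)
    denom = np.sqrt(2.0 * p * (1.0 - p))
    denom[mono] = 1.0
    Z = (d - col_mean[None, :]) / denom[None, :]
    Z[:, mono] = 0.0
    return Z, ~mono


def pca_eigenvectors(gm: GenotypeMatrix, k: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Top-k eigenvectors/eigenvalues of the genomic relationship Z Z'/m.

    Eigenvectors are unit-norm with the sign fixed so the entry of largest
    magnitude is positive.
    """
    if k > gm.n_samples:
        raise ValueError("k exceeds the number of samples")
    Z, poly = standardized_dosage(gm)
    m = max(int(poly.sum()), 1)
    G = Z @ Z.T / m
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1][:k]
    vals, vecs = vals[order], vecs[:, order]
    for j in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, j]))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vecs, vals


def snp_regression(y: np.ndarray, gm: GenotypeMatrix) -> pd.DataFrame:
    """Vectorized per-SNP simple regression of ``y`` on mean-imputed dosage.

    Returns beta, se, chisq, p; monomorphic SNPs get NaN throughout.
    """
    d = gm.dosage.astype(float)
    d[gm.dosage == MISSING] = np.nan
    mean = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), mean[None, :], d)
    n = len(y)
    yc = y - y.mean()
    dc = d - d.mean(axis=0)[None, :]
    sxx = (dc**2).sum(axis=0)
    poly = sxx > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = (dc * yc[:, None]).sum(axis=0) / sxx
        rss = (yc**2).sum() - beta**2 * sxx
        rss = np.maximum(rss, 0.0)
        se = np.sqrt(rss / (n - 2) / sxx)
        chisq = (beta / se) ** 2
    beta[~poly] = np.nan
    se[~poly] = np.nan
    chisq[~poly] = np.nan
    p = stats.chi2.sf(chisq, df=1)
    return pd.DataFrame({"beta": beta, "se": se, "chisq": chisq, "p": p})


def genomic_control(chisq: np.ndarray) -> tuple[float, np.ndarray]:
    """Genomic-control lambda and deflated statistics."""
    finite = chisq[np.isfinite(chisq)]
    if finite.size == 0:
        raise ValueError("no finite test statistics")
    lam = float(np.median(finite) / CHI2_MEDIAN_1DF)
    return lam, chisq / lam


def eigengwas_scan(
    gm: GenotypeMatrix,
    ev1: np.ndarray,
    grid: WindowGrid,
    top: float = 0.05,
    per_snp_p_cut: float | None = None,
) -> ScanResult:
    """PC1-as-phenotype genome scan with genomic-control correction.

    Window statistic = mean -log10(adjusted P) over SNPs in the window;
    selection is the empirical top fraction of window scores.  When
    ``per_snp_p_cut`` is given, an alternative per-SNP selection mode marks
    windows containing a SNP at or below that adjusted P.
    """
    res = snp_regression(np.asarray(ev1, float), gm)
    lam, chisq_adj = genomic_control(res["chisq"].to_numpy())
    p_adj = stats.chi2.sf(chisq_adj, df=1)
    neglog = -np.log10(np.clip(p_adj, 1e-300, 1.0))
    neglog = np.nan_to_num(neglog, nan=0.0)
    tested = np.isfinite(res["chisq"].to_numpy()).astype(float)
    sums, _ = _window_sums(neglog * tested, gm, grid)
    counts, _ = _window_sums(tested, gm, grid)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(counts > 0, sums / counts, np.nan)
    out = _rank_and_select(score, grid, "PDS_E", top)
    out.meta.update({"lambda_gc": lam, "n_snps_tested": int(tested.sum())})
    out.meta["snp_table"] = pd.DataFrame(
        {
            "chrom": gm.variants["chrom"],
            "pos": gm.variants["pos"],
            "chisq_adj": chisq_adj,
            "p_adj": p_adj,
        }
    )
    if per_snp_p_cut is not None:
        hit = (np.nan_to_num(p_adj, nan=1.0) <= per_snp_p_cut).astype(float)
        nhit, _ = _window_sums(hit, gm, grid)
        out.table["selected_snp_mode"] = nhit > 0
    return out


# ---------------------------------------------------------------------------
# XP-CLR
# ---------------------------------------------------------------------------


def estimate_omega(p_ref: np.ndarray, p_obj: np.ndarray) -> DriftParam:
    """Method-of-moments drift variance from genome-wide frequency pairs:
    omega = mean[(p_obj - p_ref)^2 / (p_ref (1 - p_ref))] over SNPs with
    reference frequency strictly inside (0, 1)."""
    p_ref = np.asarray(p_ref, float)
    p_obj = np.asarray(p_obj, float)
    ok = (p_ref > 0) & (p_ref < 1) & np.isfinite(p_obj)
    if not ok.any():
        raise ValueError("no SNP with reference frequency in (0,1)")
    num = (p_obj[ok] - p_ref[ok]) ** 2
    den = p_ref[ok] * (1.0 - p_ref[ok])
    return DriftParam(float(np.mean(num / den)))


def neutral_likelihood(
    k: np.ndarray,
    n: np.ndarray,
    p1: np.ndarray,
    omega: float,
    n_quad: int = 2001,
) -> np.ndarray:
    """Composite-likelihood neutral model: P(k of n | p1, omega).

    The object-population frequency p2 follows Normal(p1, omega*p1*(1-p1))
    truncated to [0,1], with the truncated tail probabilities placed as point
    masses at 0 and 1; the binomial read-out is integrated over p2 by
    trapezoid quadrature on the open interval.
    """
    if omega <= 0:
        raise ValueError("omega must be > 0 for the neutral model")
    k = np.atleast_1d(np.asarray(k, float))
    n = np.atleast_1d(np.asarray(n, float))
    p1 = np.atleast_1d(np.asarray(p1, float))
    sigma = np.sqrt(omega * p1 * (1.0 - p1))
    mass0 = stats.norm.cdf(0.0, loc=p1, scale=sigma)
    mass1 = stats.norm.sf(1.0, loc=p1, scale=sigma)
    x = np.linspace(0.0, 1.0, n_quad)
    # binomial pmf on the grid, vectorized over SNPs: shape (n_snps, n_quad)
    logpmf = stats.binom.logpmf(k[:, None], n[:, None], np.clip(x, 1e-12, 1 - 1e-12)[None, :])
    pmf = np.exp(logpmf)
    dens = stats.norm.pdf(x[None, :], loc=p1[:, None], scale=sigma[:, None])
    integral = np.trapezoid(pmf * dens, x, axis=1)
    like = integral + mass0 * (k == 0) + mass1 * (k == n)
    return like


def sweep_likelihood(
    neutral_like: np.ndarray, c: np.ndarray, k: np.ndarray, n: np.ndarray, p1: np.ndarray
) -> np.ndarray:
    """Hitchhiking mixture: with escape probability c the SNP behaves
    neutrally; otherwise the object frequency is fixed at 1 (weight p1) or 0
    (weight 1 - p1)."""
    fixed = p1 * (k == n) + (1.0 - p1) * (k == 0)
    return c * neutral_like + (1.0 - c) * fixed


def xpclr_scan(
    gm: GenotypeMatrix,
    groups: GroupAssignment,
    grid: WindowGrid,
    ref_group: str = "PIM",
    obj_group: str = "BIG",
    sweep: SweepModel | None = None,
    omega: DriftParam | None = None,
    maxsnps: int = 600,
    rec_rate_cm_mb: float = 1.0,
    top: float = 0.05,
    seed: int = 0,
    n_quad: int = 2001,
) -> ScanResult:
    """Cross-population composite likelihood ratio scan.

    For each window, CLR = 2 * [max over the selection grid of the summed
    sweep log-likelihood - summed neutral log-likelihood], evaluated at the
    window center with recombination distances from a constant cM/Mb map.
    At most ``maxsnps`` SNPs per window are used (uniform thinning, seeded).
    """
    sweep = sweep or SweepModel()
    ref_idx = groups.sample_idx(gm, ref_group)
    obj_idx = groups.sample_idx(gm, obj_group)
    p1 = gm.alt_freq(ref_idx)
    k, n = gm.alt_counts(obj_idx)
    usable = (p1 > 0) & (p1 < 1) & (n > 0)
    if omega is None:
        omega = estimate_omega(p1[usable], (k / np.maximum(n, 1))[usable])
    if omega.omega == 0:
        raise ValueError("omega = 0: degenerate neutral model")

    # neutral likelihood is window-independent -> compute once per SNP
    ln = np.full(gm.n_variants, np.nan)
    ln[usable] = neutral_likelihood(
        k[usable], n[usable], p1[usable], omega.omega, n_quad=n_quad
    )
    fixed = p1 * (k == n) + (1.0 - p1) * (k == 0)

    chrom_arr = gm.variants["chrom"].to_numpy()
    pos_arr = gm.variants["pos"].to_numpy()
    rng = np.random.default_rng(seed)
    eps = 1e-300
    clr = np.full(len(grid), np.nan)
    for w, win in enumerate(grid.windows.itertuples()):
        vmask = (chrom_arr == win.chrom) & (pos_arr >= win.start) & (pos_arr < win.end)
        snps = np.flatnonzero(vmask & usable)
        if snps.size == 0:
            continue
        if snps.size > maxsnps:
            snps = np.sort(rng.choice(snps, size=maxsnps, replace=False))
        center = 0.5 * (win.start + win.end)
        # genetic distance in Morgans from a constant-rate map; floored at
        # half a bp so escape stays possible for a SNP at the test position
        r = np.maximum(np.abs(pos_arr[snps] - center), 0.5) * rec_rate_cm_mb / 1e8
        c = sweep.escape_prob(r)  # (n_s, n_snps)
        lnw = ln[snps]
        lsw = c * lnw[None, :] + (1.0 - c) * fixed[snps][None, :]
        loglr = np.log(np.maximum(lsw, eps)).sum(axis=1) - np.log(
            np.maximum(lnw, eps)
        ).sum()
        clr[w] = 2.0 * float(loglr.max())
    out = _rank_and_select(clr, grid, "PDS_X", top)
    out.meta.update(
        {"omega": omega.omega, "maxsnps": maxsnps, "thinning_seed": seed,
         "rec_rate_cm_mb": rec_rate_cm_mb}
    )
    return out


# ---------------------------------------------------------------------------
# thresholding, merging, consensus
# ---------------------------------------------------------------------------


def empirical_threshold(values: np.ndarray, q: float = 0.05) -> float:
    """Empirical (1-q)-upper quantile with linear interpolation; +inf values
    count as above any finite threshold."""
    v = np.asarray(values, float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no finite statistic to threshold")
    finite = v[np.isfinite(v)]
    n_inf = int(np.sum(np.isposinf(v)))
    if finite.size == 0:
        return np.inf
    # rank the infinite values above every finite one when interpolating
    if n_inf == 0:
        return float(np.quantile(v, 1.0 - q))
    ranked = np.sort(finite)
    stand_in = ranked[-1]  # inf treated as >= max for quantile position
    padded = np.concatenate([ranked, np.full(n_inf, stand_in)])
    thr = float(np.quantile(padded, 1.0 - q))
    return thr


def _rank_and_select(
    statv: np.ndarray, grid: WindowGrid, method: str, top: float
) -> ScanResult:
    statv = np.asarray(statv, float)
    valid = ~np.isnan(statv)
    quantile = np.full(len(statv), np.nan)
    if valid.any():
        vals = statv[valid]
        finite_sorted = np.sort(vals[np.isfinite(vals)])
        ranks = np.searchsorted(finite_sorted, vals, side="right").astype(float)
        ranks[np.isposinf(vals)] = valid.sum()
        quantile[valid] = ranks / valid.sum()
    if top <= 0:
        threshold = np.inf
        selected = np.zeros(len(statv), dtype=bool)
    else:
        threshold = empirical_threshold(statv[valid], top) if valid.any() else np.nan
        selected = np.zeros(len(statv), dtype=bool)
        with np.errstate(invalid="ignore"):
            selected[valid] = statv[valid] >= threshold  # ties selected
    table = grid.windows.copy()
    table["stat"] = statv
    table["quantile"] = quantile
    table["selected"] = selected
    return ScanResult(method=method, table=table, threshold=float(threshold))


def merge_regions(regions, max_gap_bp: int = 100_000) -> list[GenomicRegion]:
    """Union overlapping regions and regions separated by a gap strictly less
    than ``max_gap_bp``; output sorted and non-overlapping."""
    regs = sorted(regions, key=lambda r: (r.chrom, r.start))
    out: list[GenomicRegion] = []
    for r in regs:
        if out and out[-1].chrom == r.chrom and r.start - out[-1].end < max_gap_bp:
            prev = out.pop()
            out.append(GenomicRegion(prev.chrom, prev.start, max(prev.end, r.end)))
        else:
            out.append(r)
    return out


def sweep_consensus(method_regions: dict[str, list[GenomicRegion]], genes) -> pd.DataFrame:
    """Gene-level support bitmask across scan methods.

    A gene is supported by a method iff it overlaps any of that method's
    merged regions.  Returns one row per gene overlapping at least one
    method's regions, with one boolean column per method, the concatenated
    bitmask string, and the support count.
    """
    if len(method_regions) < 2:
        raise ValueError("consensus needs at least two methods")
    methods = list(method_regions)
    support: dict[str, dict[str, bool]] = {}
    for m in methods:
        table = assign_genes(method_regions[m], genes)
        for gid in table["gene_id"].unique():
            support.setdefault(gid, {})[m] = True
    rows = []
    for gid in sorted(support):
        flags = [bool(support[gid].get(m, False)) for m in methods]
        rows.append([gid, *flags, "".join("1" if f else "0" for f in flags), sum(flags)])
    return pd.DataFrame(rows, columns=["gene_id", *methods, "bitmask", "n_methods"])


def venn_counts(consensus: pd.DataFrame, methods: list[str]) -> dict[str, int]:
    """Counts of genes per support pattern (keys are bitmask strings)."""
    return consensus.groupby("bitmask")["gene_id"].count().to_dict()
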