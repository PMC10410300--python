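"""QTL-seq style SNP-index bulked segregant analysis of an F2 cross.

Two phenotype-extreme bulks from an F2 between fully divergent parents are
sequenced to finite depth; the SNP index is the fraction of reads carrying
the cultivated-parent allele.  The delta SNP index between bulks localizes
the trait locus; significance comes from a simulation band that resamples F2
bulk composition and read depth under the no-QTL null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import WindowGrid


@dataclass
class BulkCounts:
    """Per-SNP alt/ref read counts for the high and low phenotype bulks.

    ``table`` columns: chrom, pos (0-based), high_alt, high_ref, low_alt,
    low_ref.  The alt allele is oriented to the cultivated (BIG) parent, so
    a fruit-weight-increasing locus shows delta > 0 in the high bulk.
    """

    table: pd.DataFrame
    alt_parent: str = "BIG"

    def __post_init__(self):
        cols = ["high_alt", "high_ref", "low_alt", "low_ref"]
        if (self.table[cols].to_numpy() < 0).any():
            raise ValueError("negative read counts")
        self.table = self.table.reset_index(drop=True)


def read_bulk_counts(path, alt_parent: str = "BIG") -> BulkCounts:
    """Read a tab-delimited per-SNP count table (columns chrom, pos, high_alt,
    high_ref, low_alt, low_ref; pos 1-based in the file)."""
    df = pd.read_csv(path, sep="\t")
    df["pos"] = df["pos"] - 1
    return BulkCounts(df, alt_parent=alt_parent)


def write_bulk_counts(bulk: BulkCounts, path) -> None:
    df = bulk.table.copy()
    df["pos"] = df["pos"] + 1
    df.to_csv(path, sep="\t", index=False)


def snp_index(
    bulk: BulkCounts, bulk_id: str, min_depth: int = 10
) -> tuple[pd.Series, int]:
    """Per-SNP index alt/(alt+ref) for one bulk ('high' or 'low').

    SNPs below ``min_depth`` (or with zero depth) are dropped for that bulk;
    returns (index keyed by table row, number of dropped SNPs).
    """
    alt = bulk.table[f"{bulk_id}_alt"].to_numpy(float)
    ref = bulk.table[f"{bulk_id}_ref"].to_numpy(float)
    depth = alt + ref
    keep = depth >= max(min_depth, 1)
    idx = pd.Series(alt[keep] / depth[keep], index=bulk.table.index[keep])
    return idx, int((~keep).sum())


def windowed_index(
    pos: np.ndarray, indices: np.ndarray, grid: WindowGrid, chrom: np.ndarray
) -> np.ndarray:
    """Unweighted mean SNP index per window; NaN where the window is empty."""
    pos = np.asarray(pos)
    indices = np.asarray(indices, float)
    chrom = np.asarray(chrom)
    out = np.full(len(grid), np.nan)
    for c in pd.unique(grid.windows["chrom"]):
        vmask = chrom == c
        p = pos[vmask]
        v = indices[vmask]
        order = np.argsort(p)
        p, v = p[order], v[order]
        cs = np.concatenate([[0.0], np.cumsum(v)])
        wmask = grid.windows["chrom"].to_numpy() == c
        lo = np.searchsorted(p, grid.windows["start"].to_numpy()[wmask], side="left")
        hi = np.searchsorted(p, grid.windows["end"].to_numpy()[wmask], side="left")
        cnt = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            out[wmask] = np.where(cnt > 0, (cs[hi] - cs[lo]) / cnt, np.nan)
    return out


def _null_band(
    n_snps: int,
    depths: np.ndarray,
    bulk_sizes: tuple[int, int],
    n_sims: int,
    min_depth: int,
    rng: np.random.Generator,
) -> tuple[float, float, float, float]:
    """Simulated quantiles of the windowed delta index under the no-QTL null.

    SNPs within one window are tightly linked in an F2, so one bulk allele
    frequency per window per bulk is drawn (Binomial(2m, 1/2)/2m) and shared
    across the window's SNPs; read depths are resampled from the observed
    depths and reads are binomial given the bulk frequency.
    """
    deltas = np.empty(n_sims)
    mh, ml = bulk_sizes
    qh = rng.binomial(2 * mh, 0.5, size=n_sims) / (2.0 * mh)
    ql = rng.binomial(2 * ml, 0.5, size=n_sims) / (2.0 * ml)
    dh = rng.choice(depths, size=(n_sims, n_snps), replace=True)
    dl = rng.choice(depths, size=(n_sims, n_snps), replace=True)
    ah = rng.binomial(dh.astype(int), qh[:, None])
    al = rng.binomial(dl.astype(int), ql[:, None])
    idx_h = (ah / dh).mean(axis=1)
    idx_l = (al / dl).mean(axis=1)
    deltas = idx_h - idx_l
    q = np.quantile(deltas, [0.025, 0.975, 0.005, 0.995])
    return float(q[0]), float(q[1]), float(q[2]), float(q[3])


def delta_index(
    bulk: BulkCounts,
    grid: WindowGrid,
    bulk_sizes: tuple[int, int] = (30, 30),
    min_depth: int = 10,
    n_sims: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Windowed delta SNP index with 95%/99% simulation bands and peak calls.

    Returns one row per window: idx_high, idx_low, delta, band quantiles and
    ``peak_id`` (consecutive windows with delta outside the 99% band share an
    id; NaN elsewhere).
    """
    if bulk_sizes is None:
        raise ValueError("bulk sizes are required for the null simulation")
    idx_h, _ = snp_index(bulk, "high", min_depth)
    idx_l, _ = snp_index(bulk, "low", min_depth)
    shared = idx_h.index.intersection(idx_l.index)
    tab = bulk.table.loc[shared]
    chrom = tab["chrom"].to_numpy()
    pos = tab["pos"].to_numpy()
    depths = (
        tab[["high_alt", "high_ref"]].sum(axis=1).to_numpy()
        .astype(int)
    )
    wh = windowed_index(pos, idx_h.loc[shared].to_numpy(), grid, chrom)
    wl = windowed_index(pos, idx_l.loc[shared].to_numpy(), grid, chrom)
    delta = wh - wl

    rng = np.random.default_rng(seed)
    out = grid.windows.copy()
    out["idx_high"] = wh
    out["idx_low"] = wl
    out["delta"] = delta
    bands = np.full((len(grid), 4), np.nan)
    # group windows by SNP count so each band simulation is vectorized
    counts = np.zeros(len(grid), dtype=int)
    for c in pd.unique(grid.windows["chrom"]):
        vmask = chrom == c
        p = np.sort(pos[vmask])
        wmask = grid.windows["chrom"].to_numpy() == c
        lo = np.searchsorted(p, grid.windows["start"].to_numpy()[wmask])
        hi = np.searchsorted(p, grid.windows["end"].to_numpy()[wmask])
        counts[wmask] = hi - lo
    for w in range(len(grid)):
        if counts[w] == 0 or np.isnan(delta[w]):
            continue
        bands[w] = _null_band(
            int(counts[w]), depths, bulk_sizes, n_sims, min_depth, rng
        )
    out[["band95_lo", "band95_hi", "band99_lo", "band99_hi"]] = bands
    outside99 = (delta < bands[:, 2]) | (delta > bands[:, 3])
    outside99 &= ~np.isnan(delta)
    peak_id = np.full(len(grid), np.nan)
    pid = 0
    prev = False
    for w in range(len(grid)):
        if outside99[w]:
            if not prev:
                pid += 1
            peak_id[w] = pid
        prev = bool(outside99[w])
    out["peak_id"] = peak_id
    return out
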