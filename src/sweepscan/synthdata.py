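"""Synthetic cohorts with the statistical structure the pipeline assumes.

Two populations (wild PIM, cultivated BIG) diverge by drift under the
Balding-Nichols model; designated sweep regions use a much larger drift
parameter in BIG only, collapsing diversity there.  Quantitative phenotypes
combine a few major loci with a kinship-structured polygenic background, and
an F2 cross between fully divergent parents yields phenotype-extreme bulks
sequenced to finite depth.

All generators are pure functions of (scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bsa import BulkCounts
from .genodata import GenomicRegion, GenotypeMatrix, GroupAssignment


@dataclass(frozen=True)
class QTL:
    chrom: str
    pos: int  # 0-based; must coincide with a simulated SNP
    frac: float  # fraction of phenotypic variance explained
    origin: str = "BIG"  # which parental allele increases the trait


@dataclass
class SimScenario:
    """Full parameterization of the synthetic cohort.

    Defaults mirror the reference cohort (53 wild + 166 cultivated
    accessions) at desk scale: 2 chromosomes of 5 Mb, 10,000 SNPs, three
    300-kb sweeps with strong drift in the cultivated group.
    """

    n_pim: int = 53
    n_big: int = 166
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    n_snps: int = 10_000
    f_pim: float = 0.1
    f_big: float = 0.1
    f_sweep: float = 0.9
    sweeps: list = field(
        default_factory=lambda: [
            GenomicRegion("chr1", 1_000_000, 1_300_000),
            GenomicRegion("chr1", 3_200_000, 3_500_000),
            GenomicRegion("chr2", 2_000_000, 2_300_000),
        ]
    )
    qtls: list = field(default_factory=list)  # filled against simulated SNPs
    h2_polygenic: float = 0.3
    bulk_sizes: tuple = (30, 30)
    mean_depth: float = 30.0
    seed: int = 42

    def __post_init__(self):
        for f in (self.f_pim, self.f_big):
            if not 0 < f < 1:
                raise ValueError("drift F must be in (0, 1)")
        if not self.f_sweep > self.f_big:
            raise ValueError("sweep drift must exceed the neutral BIG drift")


def _balding_nichols(
    rng: np.random.Generator, p_anc: np.ndarray, F: np.ndarray
) -> np.ndarray:
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    return rng.beta(a, b)


def simulate_divergence(scn: SimScenario, seed: int | None = None):
    """Genotypes for the two-population cohort.

    Returns ``(gm, groups, truth)``; ``truth`` records the planted sweep
    regions and the per-population allele frequencies.
    """
    rng = np.random.default_rng(scn.seed if seed is None else seed)
    total_len = sum(scn.chrom_lengths.values())
    chroms, poss = [], []
    for chrom, length in scn.chrom_lengths.items():
        n = int(round(scn.n_snps * length / total_len))
        pos = np.sort(rng.choice(length, size=n, replace=False))
        chroms.extend([chrom] * n)
        poss.extend(pos.tolist())
    chrom_arr = np.array(chroms)
    pos_arr = np.array(poss)
    m = len(pos_arr)

    p_anc = rng.uniform(0.05, 0.95, size=m)
    in_sweep = np.zeros(m, dtype=bool)
    for r in scn.sweeps:
        in_sweep |= (chrom_arr == r.chrom) & (pos_arr >= r.start) & (pos_arr < r.end)
    f_big = np.where(in_sweep, scn.f_sweep, scn.f_big)
    p_pim = _balding_nichols(rng, p_anc, np.full(m, scn.f_pim))
    p_big = _balding_nichols(rng, p_anc, f_big)

    geno_pim = rng.binomial(2, p_pim, size=(scn.n_pim, m)).astype(np.int16)
    geno_big = rng.binomial(2, p_big, size=(scn.n_big, m)).astype(np.int16)
    samples = [f"PIM_{i:03d}" for i in range(scn.n_pim)] + [
        f"BIG_{i:03d}" for i in range(scn.n_big)
    ]
    gm = GenotypeMatrix(
        samples=samples,
        variants=pd.DataFrame(
            {"chrom": chrom_arr, "pos": pos_arr, "ref": "A", "alt": "G"}
        ),
        dosage=np.vstack([geno_pim, geno_big]) if scn.n_pim else geno_big,
    )
    groups = GroupAssignment(
        pd.Series(
            ["PIM"] * scn.n_pim + ["BIG"] * scn.n_big, index=samples, dtype=str
        )
    )
    truth = {
        "sweeps": [(r.chrom, r.start, r.end) for r in scn.sweeps],
        "p_anc": p_anc,
        "p_pim": p_pim,
        "p_big": p_big,
        "in_sweep": in_sweep,
        "seed": scn.seed if seed is None else seed,
    }
    return gm, groups, truth


def simulate_phenotype(
    gm: GenotypeMatrix,
    qtls: list[QTL],
    h2_polygenic: float,
    seed: int = 0,
    trait: str = "FW",
):
    """Quantitative trait = major QTL effects + kinship-structured polygenic
    background + residual noise, with every component scaled to its exact
    empirical variance fraction.  Returns (PhenotypeTable, truth)."""
    frac_sum = sum(q.frac for q in qtls) + h2_polygenic
    if frac_sum > 1:
        raise ValueError("variance fractions sum above 1")
    rng = np.random.default_rng(seed)
    n = gm.n_samples
    y = np.zeros(n)
    truth_qtls = []
    for q in qtls:
        j = gm.variant_index(q.chrom, q.pos)
        g = gm.dosage[:, j].astype(float)
        g[gm.dosage[:, j] < 0] = np.nan
        g = np.where(np.isnan(g), np.nanmean(g), g)
        if g.std() == 0:
            raise ValueError(f"QTL SNP {q.chrom}:{q.pos} is monomorphic")
        sign = 1.0 if q.origin == "BIG" else -1.0
        comp = sign * (g - g.mean()) / g.std() * np.sqrt(q.frac)
        y += comp
        truth_qtls.append({"chrom": q.chrom, "pos": q.pos, "frac": q.frac})
    if h2_polygenic > 0:
        from .selscan import standardized_dosage

        Z, poly = standardized_dosage(gm)
        u = Z @ rng.standard_normal(gm.n_variants) / np.sqrt(max(poly.sum(), 1))
        if u.std() > 0:
            y += (u - u.mean()) / u.std() * np.sqrt(h2_polygenic)
    resid_frac = 1.0 - frac_sum
    e = rng.standard_normal(n)
    if resid_frac > 0:
        y += (e - e.mean()) / e.std() * np.sqrt(resid_frac)
    pheno = pd.DataFrame({trait: y}, index=gm.samples)
    truth = {"qtls": truth_qtls, "h2_polygenic": h2_polygenic, "seed": seed}
    return pheno, truth


def correlated_traits(
    pheno: pd.DataFrame,
    base_trait: str,
    names: list[str],
    r: float = 0.6,
    seed: int = 0,
) -> pd.DataFrame:
    """Add traits correlated with ``base_trait`` at Pearson r (in expectation)."""
    rng = np.random.default_rng(seed)
    y = pheno[base_trait].to_numpy()
    y_std = (y - y.mean()) / y.std()
    out = pheno.copy()
    for name in names:
        noise = rng.standard_normal(len(y))
        noise = (noise - noise.mean()) / noise.std()
        out[name] = r * y_std + np.sqrt(1 - r**2) * noise
    return out


def simulate_f2_bulks(
    chrom_length: int = 65_000_000,
    n_snps: int = 2_000,
    qtl_pos: int | None = 63_400_000,
    qtl_frac: float = 0.5,
    n_f2: int = 500,
    bulk_sizes: tuple[int, int] = (30, 30),
    mean_depth: float = 30.0,
    rec_rate_cm_mb: float = 1.0,
    seed: int = 0,
    chrom: str = "chr9",
):
    """F2 bulks from a cross of fully divergent homozygous parents.

    Gametes recombine under a Haldane map at a constant cM/Mb rate; the
    phenotype is the QTL genotype effect plus Gaussian noise; bulks are the
    phenotype tails; reads per SNP are Binomial(Poisson(mean_depth), bulk
    allele frequency).  The alt allele is the cultivated (high) parent's.

    Returns (BulkCounts, truth).
    """
    mh, ml = bulk_sizes
    if mh > n_f2 // 2 or ml > n_f2 // 2:
        raise ValueError("bulk size exceeds half the F2 population")
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.choice(chrom_length, size=n_snps, replace=False))
    if qtl_pos is not None:
        j_qtl = int(np.argmin(np.abs(pos - qtl_pos)))
    morgans = pos * rec_rate_cm_mb / 1e8

    def gametes(n):
        """Alt-allele indicator per (gamete, SNP) under a Haldane map."""
        out = np.empty((n, n_snps), dtype=np.int8)
        for i in range(n):
            # crossover points as a Poisson process on the genetic map
            lam = morgans[-1]
            n_co = rng.poisson(lam)
            breaks = np.sort(rng.uniform(0, morgans[-1], size=n_co))
            phase = rng.integers(0, 2)
            seg = phase + np.searchsorted(breaks, morgans, side="right")
            out[i] = seg % 2
        return out

    g1 = gametes(n_f2)
    g2 = gametes(n_f2)
    geno = (g1 + g2).astype(np.int8)  # alt dosage per F2 x SNP

    if qtl_pos is not None and qtl_frac > 0:
        gq = geno[:, j_qtl].astype(float)
        effect = np.sqrt(qtl_frac / max(gq.var(), 1e-12))
        noise_sd = np.sqrt(max(1.0 - qtl_frac, 1e-12))
    else:
        gq = np.zeros(n_f2)
        effect, noise_sd = 0.0, 1.0
    phen = effect * (gq - gq.mean()) + noise_sd * rng.standard_normal(n_f2)
    order = np.argsort(phen)
    low_bulk = order[:ml]
    high_bulk = order[-mh:]

    rows = {"chrom": chrom, "pos": pos}
    for name, members in (("high", high_bulk), ("low", low_bulk)):
        q = geno[members].mean(axis=0) / 2.0
        depth = rng.poisson(mean_depth, size=n_snps)
        alt = rng.binomial(depth, q)
        rows[f"{name}_alt"] = alt
        rows[f"{name}_ref"] = depth - alt
    truth = {
        "qtl_chrom": chrom,
        "qtl_pos": int(pos[j_qtl]) if qtl_pos is not None else None,
        "qtl_frac": qtl_frac,
        "seed": seed,
    }
    return BulkCounts(pd.DataFrame(rows)), truth


def default_qtls(gm: GenotypeMatrix, truth: dict, seed: int = 0) -> list[QTL]:
    """Place one 20%-variance QTL at a polymorphic SNP inside the last planted
    sweep (or mid-genome when no sweeps exist)."""
    rng = np.random.default_rng(seed)
    chrom_arr = gm.variants["chrom"].to_numpy()
    pos_arr = gm.variants["pos"].to_numpy()
    maf = gm.maf()
    if truth["sweeps"]:
        c, s, e = truth["sweeps"][-1]
        cand = np.flatnonzero(
            (chrom_arr == c) & (pos_arr >= s) & (pos_arr < e) & (maf > 0.05)
        )
    else:
        cand = np.flatnonzero(maf > 0.05)
    if cand.size == 0:
        raise ValueError("no polymorphic SNP available for a QTL")
    j = int(cand[rng.integers(cand.size)])
    return [QTL(chrom=chrom_arr[j], pos=int(pos_arr[j]), frac=0.2)]
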