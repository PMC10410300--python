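"""Locus-level follow-up: group allele frequencies, multilocus R/A haplotype
combinations, trait tests and correlations, and the accession NJ tree."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genodata import MISSING, GenotypeMatrix, GroupAssignment


def allele_freq_by_group(
    gm: GenotypeMatrix, chrom: str, pos: int, groups: GroupAssignment
) -> pd.DataFrame:
    """Per-group alt frequency and genotype-class counts at one SNP.

    ``pos`` is 0-based internal.  Rows indexed by group with columns
    ``alt_freq`` and ``n_hom_ref/n_het/n_hom_alt/n_missing``.
    """
    j = gm.variant_index(chrom, pos)
    rows = {}
    for g in groups.groups():
        idx = groups.sample_idx(gm, g)
        d = gm.dosage[idx, j]
        called = d != MISSING
        n_alleles = 2 * called.sum()
        freq = d[called].sum() / n_alleles if n_alleles else np.nan
        rows[g] = {
            "alt_freq": freq,
            "n_hom_ref": int((d == 0).sum()),
            "n_het": int((d == 1).sum()),
            "n_hom_alt": int((d == 2).sum()),
            "n_missing": int((~called).sum()),
        }
    return pd.DataFrame(rows).T


def multilocus_haplotype(
    gm: GenotypeMatrix,
    loci: list[tuple[str, int]],
    groups: GroupAssignment,
    reference_group: str = "PIM",
):
    """Label samples by homozygous allele combination across loci.

    Per locus, "R" is the major allele of the reference group and "A" the
    alternate; samples heterozygous or missing at any locus are excluded
    (count returned).  Returns (per-sample label Series, per-group frequency
    table, n_excluded).
    """
    ref_idx = groups.sample_idx(gm, reference_group)
    cols, r_is_alt = [], []
    for chrom, pos in loci:
        j = gm.variant_index(chrom, pos)
        d_ref = gm.dosage[ref_idx, j]
        called = d_ref != MISSING
        if not called.any():
            raise ValueError(f"locus {chrom}:{pos} uncalled in {reference_group}")
        alt_freq = d_ref[called].sum() / (2 * called.sum())
        mono_no_alt = {0.0} == set(np.unique(d_ref[called])) and not (
            (gm.dosage[:, j] > 0) & (gm.dosage[:, j] != MISSING)
        ).any()
        if mono_no_alt:
            raise ValueError(
                f"locus {chrom}:{pos} monomorphic in {reference_group} with no "
                "alternate allele anywhere"
            )
        r_is_alt.append(alt_freq > 0.5)
        cols.append(gm.dosage[:, j])
    D = np.column_stack(cols)
    homo = np.all((D == 0) | (D == 2), axis=1)
    labels = {}
    for i in np.flatnonzero(homo):
        lab = []
        for l, d in enumerate(D[i]):
            is_alt = d == 2
            lab.append("R" if is_alt == r_is_alt[l] else "A")
        labels[gm.samples[i]] = "".join(lab)
    label_series = pd.Series(labels, dtype=str)
    n_excluded = int((~homo).sum())
    rows = []
    for g in groups.groups():
        members = set(groups.labels.index[groups.labels == g])
        sub = label_series[label_series.index.isin(members)]
        total = len(sub)
        for lab, cnt in sub.value_counts().items():
            rows.append((g, lab, int(cnt), cnt / total))
    freq = pd.DataFrame(rows, columns=["group", "label", "count", "freq"])
    return label_series, freq, n_excluded


def trait_group_tests(pheno: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """One-way ANOVA (and rank-sum for 2 groups) of every trait across label
    groups; groups with < 2 observations are dropped from that trait's test."""
    rows = []
    for trait in pheno.columns:
        series = pheno[trait]
        samples = series.dropna().index.intersection(labels.index)
        by_group = [
            series.loc[s].to_numpy()
            for _, s in pd.Series(samples).groupby(labels.loc[samples].values)
            if len(s) >= 2
        ]
        if len(by_group) < 2:
            rows.append((trait, np.nan, np.nan, np.nan, np.nan))
            continue
        flat = np.concatenate(by_group)
        if np.ptp(flat) == 0:
            rows.append((trait, np.nan, np.nan, np.nan, np.nan))
            continue
        f, p_anova = stats.f_oneway(*by_group)
        if len(by_group) == 2:
            w, p_rs = stats.ranksums(by_group[0], by_group[1])
        else:
            w, p_rs = np.nan, np.nan
        rows.append((trait, f, p_anova, w, p_rs))
    return pd.DataFrame(
        rows, columns=["trait", "anova_F", "anova_p", "ranksum_W", "ranksum_p"]
    )


def trait_correlations(
    pheno: pd.DataFrame, target_trait: str, r_min: float = 0.5
) -> pd.DataFrame:
    """Pearson r of every other trait against the target (pairwise-complete,
    >= 3 shared observations); returns traits with r strictly above r_min."""
    target = pheno[target_trait]
    rows = []
    for trait in pheno.columns:
        if trait == target_trait:
            continue
        pair = pd.concat([target, pheno[trait]], axis=1).dropna()
        if len(pair) < 3:
            continue
        x, y = pair.iloc[:, 0], pair.iloc[:, 1]
        if x.std() == 0 or y.std() == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        rows.append((trait, r))
    df = pd.DataFrame(rows, columns=["trait", "r"])
    return df[df["r"] > r_min].reset_index(drop=True)


def ibs_distance(gm: GenotypeMatrix) -> pd.DataFrame:
    """1 - IBS distance matrix over shared non-missing SNPs.

    IBS(i,j) = mean of (2 - |g_i - g_j|)/2; a semimetric with zero diagonal.
    """
    d = gm.dosage
    valid = (d != MISSING).astype(float)
    I = [(d == v).astype(float) * valid for v in (0, 1, 2)]
    shared = valid @ valid.T
    absdiff = (
        I[0] @ I[1].T + I[1] @ I[0].T + I[1] @ I[2].T + I[2] @ I[1].T
        + 2.0 * (I[0] @ I[2].T + I[2] @ I[0].T)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(shared > 0, absdiff / (2.0 * shared), np.nan)
    np.fill_diagonal(dist, 0.0)
    return pd.DataFrame(dist, index=gm.samples, columns=gm.samples)


def nj_tree(gm: GenotypeMatrix | None = None, dist: pd.DataFrame | None = None) -> str:
    """Neighbor-joining tree (newick) on the 1-IBS distance matrix.

    Samples are sorted lexicographically before clustering so ties break
    deterministically; negative branch lengths are clamped to zero.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if dist is None:
        if gm is None or gm.n_samples < 3:
            raise ValueError("need >= 3 samples for a tree")
        dist = ibs_distance(gm)
    if len(dist) < 3:
        raise ValueError("need >= 3 samples for a tree")
    order = sorted(dist.index)
    dm = DistanceMatrix(dist.loc[order, order].to_numpy(), ids=order)
    tree = nj(dm, neg_as_zero=True)
    return str(tree).strip()


def is_monophyletic(newick: str, members: set[str]) -> bool:
    """True when some edge of the (unrooted) tree splits ``members`` exactly
    from the remaining leaves."""
    from io import StringIO

    from skbio import TreeNode

    tree = TreeNode.read(StringIO(newick))
    leaves = {t.name for t in tree.tips()}
    others = leaves - members
    if not members <= leaves:
        raise ValueError("members not all present in the tree")
    for node in tree.non_tips(include_self=True):
        clade = {t.name for t in node.tips()}
        if clade == members or clade == others:
            return True
    return False
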