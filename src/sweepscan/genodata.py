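"""Genotype, annotation and phenotype containers plus all coordinate logic.

Every other module consumes the types defined here.  Internal coordinates are
0-based half-open throughout; conversion to/from the 1-based conventions of
VCF and GFF3 happens only at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1  # sentinel for a missing diploid dosage


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages for a sample cohort.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers (VCF header order is preserved on read).
    variants : pandas.DataFrame
        One row per SNP with columns ``chrom`` (str), ``pos`` (int, 0-based),
        ``ref`` and ``alt`` (single-base allele symbols).  Positions are
        strictly increasing within a chromosome.
    dosage : numpy.ndarray
        ``(n_samples, n_variants)`` int16 array of alt-allele counts
        {0, 1, 2}; missing genotypes are stored as ``MISSING`` (-1).
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0,1,2} or missing")
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            if not np.all(np.diff(sub["pos"].to_numpy()) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing genotype calls."""
        return self.dosage != MISSING

    def alt_counts(self, sample_idx: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-variant (alt allele count, total called alleles).

        Restricted to ``sample_idx`` rows when given.
        """
        d = self.dosage if sample_idx is None else self.dosage[sample_idx]
        called = d != MISSING
        a = np.where(called, d, 0).sum(axis=0).astype(float)
        n = 2.0 * called.sum(axis=0)
        return a, n

    def alt_freq(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Alt-allele frequency from non-missing calls; NaN where uncalled."""
        a, n = self.alt_counts(sample_idx)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, a / n, np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return (self.dosage == MISSING).mean(axis=0)

    def take_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[idx],
            dosage=self.dosage[:, idx],
        )

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            variants=self.variants,
            dosage=self.dosage[idx],
        )

    def variant_index(self, chrom: str, pos: int) -> int:
        """Row index of the SNP at 0-based ``pos`` on ``chrom`` (error if absent)."""
        hit = np.flatnonzero(
            (self.variants["chrom"].to_numpy() == chrom)
            & (self.variants["pos"].to_numpy() == pos)
        )
        if hit.size == 0:
            raise KeyError(f"no SNP at {chrom}:{pos} (0-based)")
        return int(hit[0])


@dataclass
class GroupAssignment:
    """Sample -> group label map (PIM/BIG in the reference cohort, extensible)."""

    labels: pd.Series  # index = sample ID, value = group label

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels, dtype=str)
        if self.labels.index.duplicated().any():
            raise ValueError("duplicate sample IDs in group assignment")

    def groups(self) -> list[str]:
        return sorted(self.labels.unique())

    def sample_idx(self, gm: GenotypeMatrix, group: str) -> np.ndarray:
        """Row indices of ``gm.samples`` belonging to ``group``."""
        members = set(self.labels.index[self.labels == group])
        if not members:
            raise KeyError(f"group {group!r} has no samples")
        idx = np.array([i for i, s in enumerate(gm.samples) if s in members])
        if idx.size == 0:
            raise KeyError(f"group {group!r} has no samples in the matrix")
        return idx

    def validate_covers(self, samples: list[str]) -> None:
        missing = [s for s in samples if s not in self.labels.index]
        if missing:
            raise ValueError(f"samples absent from group table: {missing}")


@dataclass(frozen=True)
class GenomicRegion:
    """Half-open interval [start, end) in 0-based coordinates."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty region {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class WindowGrid:
    """Sliding windows over chromosomes; ``step <= size`` enforced."""

    size: int
    step: int
    windows: pd.DataFrame  # columns chrom, start, end

    def __post_init__(self) -> None:
        if self.step > self.size:
            raise ValueError("window step must not exceed window size")
        self.windows = self.windows.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.windows)

    def regions(self) -> list[GenomicRegion]:
        return [
            GenomicRegion(r.chrom, int(r.start), int(r.end))
            for r in self.windows.itertuples()
        ]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str = "+"

    @property
    def span(self) -> GenomicRegion:
        return GenomicRegion(self.chrom, self.start, self.end)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_groups(path) -> GroupAssignment:
    """Read a tab-delimited sample/group table (header row required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.lower() for c in df.columns]
    return GroupAssignment(pd.Series(df["group"].values, index=df["sample"].values))


def read_vcf(path, group_table_path=None):
    """Load biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Non-biallelic and non-SNP records are skipped (count logged and returned
    in the matrix metadata is not kept — the skip count is the second return
    value when no group table is given, or logged otherwise).

    Returns ``(gm, groups)`` when ``group_table_path`` is given, else
    ``(gm, n_skipped)``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms, poss, refs, alts, rows = [], [], [], [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        # gts012: 0/1/2 = alt dosage, 3 = missing
        g = np.asarray(v.gt_types, dtype=np.int16)
        g[g == 3] = MISSING
        chroms.append(v.CHROM)
        poss.append(v.POS - 1)  # to 0-based
        refs.append(v.REF)
        alts.append(v.ALT[0])
        rows.append(g)
    if not rows:
        raise ValueError(f"no usable biallelic SNP records in {path}")
    if n_skipped:
        log.info("read_vcf: skipped %d non-biallelic/non-SNP records", n_skipped)
    gm = GenotypeMatrix(
        samples=samples,
        variants=pd.DataFrame(
            {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts}
        ),
        dosage=np.vstack(rows).T,
    )
    if group_table_path is not None:
        groups = read_groups(group_table_path)
        groups.validate_covers(samples)
        return gm, groups
    return gm, n_skipped


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path, extra_header: list[str] | None = None) -> None:
    """Write a minimal GT-only VCF 4.2 file (positions back to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        for line in extra_header or []:
            fh.write(f"##{line}\n")
        for chrom, sub in gm.variants.groupby("chrom", sort=False):
            fh.write(f"##contig=<ID={chrom},length={int(sub['pos'].max()) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        for j, v in enumerate(gm.variants.itertuples()):
            gts = "\t".join(_GT_STRING[int(d)] for d in gm.dosage[:, j])
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_bed(regions, path, names: list[str] | None = None) -> None:
    """Write regions as BED (natively 0-based half-open)."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            name = names[i] if names else r.name
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\n")


def read_gff3(path) -> list[GeneModel]:
    """Read gene features from a GFF3 file (gffutils, in-memory db)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=feat.seqid,
                start=feat.start - 1,  # GFF3 is 1-based closed
                end=feat.end,
                strand=feat.strand or "+",
            )
        )
    if len({g.gene_id for g in genes}) != len(genes):
        raise ValueError("duplicate gene IDs in GFF3")
    return sorted(genes, key=lambda g: (g.chrom, g.start))


def read_phenotypes(path) -> pd.DataFrame:
    """Read a tab-delimited phenotype table (sample column + traits; NA = missing)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df = df.set_index(df.columns[0])
    if df.columns.duplicated().any():
        raise ValueError("duplicate trait names in phenotype table")
    return df


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", na_rep="NA", index_label="sample")


# ---------------------------------------------------------------------------
# filtering / windowing / overlap
# ---------------------------------------------------------------------------


def filter_variants(
    gm: GenotypeMatrix, maf_min: float = 0.05, missing_max: float = 0.10
) -> GenotypeMatrix:
    """Keep variants with MAF strictly above ``maf_min`` and missing fraction
    strictly below ``missing_max`` (both computed from non-missing calls)."""
    if not (0 <= maf_min < 0.5):
        raise ValueError("maf_min must be in [0, 0.5)")
    if not (0 <= missing_max <= 1):
        raise ValueError("missing_max must be in [0, 1]")
    keep = (gm.maf() > maf_min) & (gm.missing_rate() < missing_max)
    keep &= ~np.isnan(gm.alt_freq())
    if not keep.any():
        log.warning("filter_variants removed every variant")
    return gm.take_variants(np.flatnonzero(keep))


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, missing excluded
    pairwise; monomorphic pairs return 0."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv, yv = x[ok].astype(float), y[ok].astype(float)
    if xv.std() == 0 or yv.std() == 0:
        return 0.0
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def ld_prune(
    gm: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.2,
) -> GenotypeMatrix:
    """Greedy within-window LD pruning of dosage r².

    For every SNP pair inside a sliding window of ``window_snps`` markers with
    r² strictly above ``r2_max``, the member with the lower MAF is dropped
    (tie: the downstream SNP dies).  Windows advance by ``step_snps`` and do
    not cross chromosome boundaries.  Deterministic for a fixed input.
    """
    if not window_snps >= step_snps >= 1:
        raise ValueError("require window_snps >= step_snps >= 1")
    maf = gm.maf()
    removed = np.zeros(gm.n_variants, dtype=bool)
    chrom_arr = gm.variants["chrom"].to_numpy()
    for chrom in pd.unique(chrom_arr):
        idx = np.flatnonzero(chrom_arr == chrom)
        start = 0
        while start < len(idx):
            win = idx[start : start + window_snps]
            for a in range(len(win)):
                i = win[a]
                if removed[i]:
                    continue
                for b in range(a + 1, len(win)):
                    j = win[b]
                    if removed[j] or removed[i]:
                        continue
                    if _pairwise_r2(gm.dosage[:, i], gm.dosage[:, j]) > r2_max:
                        # drop the lower-MAF member; tie -> later position
                        if maf[i] < maf[j]:
                            removed[i] = True
                        else:
                            removed[j] = True
            if start + window_snps >= len(idx):
                break
            start += step_snps
    return gm.take_variants(np.flatnonzero(~removed))


def make_windows(chrom_lengths: dict[str, int], size_bp: int, step_bp: int) -> WindowGrid:
    """Tile each chromosome with sliding windows.

    Starts advance by ``step_bp``; generation stops at the first window whose
    end reaches the chromosome end, so a trailing partial window is kept only
    when needed to cover the tail.
    """
    if not size_bp >= step_bp >= 1:
        raise ValueError("require size_bp >= step_bp >= 1")
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom}")
        start = 0
        while True:
            end = min(start + size_bp, length)
            if end <= start:
                break
            rows.append((chrom, start, end))
            if end >= length:
                break
            start += step_bp
    return WindowGrid(
        size=size_bp,
        step=step_bp,
        windows=pd.DataFrame(rows, columns=["chrom", "start", "end"]),
    )


def assign_genes(regions, genes) -> pd.DataFrame:
    """Table of (gene_id, region_id) for every gene/region pair sharing >= 1 bp.

    Overlap, not containment: a gene straddling a region edge is assigned.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    region_list = list(regions)
    for ri, r in enumerate(region_list):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, ri)
    rows = []
    for g in genes:
        tree = trees.get(g.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(g.start, g.end), key=lambda iv: iv.begin):
            rows.append((g.gene_id, region_list[iv.data].name))
    return pd.DataFrame(rows, columns=["gene_id", "region_id"])
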