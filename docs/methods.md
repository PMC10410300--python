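# Methods

This note records the models implemented in `sweepscan`, their assumptions,
the defaults and why they were chosen, and what the synthetic-data tests do
and do not demonstrate about real data.

## Data model and coordinates

All genotype data live in a `GenotypeMatrix`: biallelic SNPs only, diploid
dosages in {0,1,2} with explicit missingness, positions strictly increasing
per chromosome. Internal coordinates are 0-based half-open everywhere;
1-based conventions (VCF, GFF3) are converted at the I/O boundary only, so
all interval arithmetic uses a single convention. "Gene within a region"
means ≥ 1 bp overlap of the gene span, not containment — boundary genes at
sweep edges are biologically relevant and containment would drop them.

Variant filtering uses strict inequalities (MAF > 0.05, missing < 0.10),
with MAF computed from non-missing alleles only. LD pruning is greedy within
sliding SNP windows (default 50 SNPs, step 5, r² > 0.2): the lower-MAF
member of an offending pair is removed, ties remove the downstream SNP.
Missing dosages are excluded pairwise from r² (no imputation); monomorphic
pairs are treated as r² = 0. Note that with step > 1 a pair at distance
greater than window − step may never share a window, exactly as in the usual
sliding-window implementations; the no-surviving-pair guarantee is strict
only at step 1.

Sliding windows (default 100 kb, step 10 kb) advance until the first window
whose end reaches the chromosome end; a trailing partial window is kept only
when needed to cover the tail.

## Selection scans

**π and π-ratio.** Site diversity is the unbiased pairwise estimator
2a(n−a)/(n(n−1)); window π divides the summed site diversity by window
length in bp, treating non-variant positions as invariant (the
whole-genome-resequencing assumption; a callability mask is a config hook,
not implemented). Windows with π_BIG = 0 and π_PIM > 0 get an infinite
ratio and outrank all finite windows; windows with both zero are excluded
from ranking. Empirical thresholds are upper quantiles with linear
interpolation, and ties at the threshold are selected (≥ comparisons).

**EigenGWAS.** PCA uses (g − 2p)/√(2p(1−p)) standardization with per-variant
mean imputation, eigenvectors sign-fixed so the largest-magnitude entry is
positive. Each SNP is tested by simple regression of PC1 on dosage; the χ²
statistics are deflated by λ = median(χ²)/0.4549 before P-values are taken.
The window statistic is the mean of −log₁₀P over the window's SNPs (the
alternative per-SNP P cutoff mode is exposed as well, since either reading
of "top windows" is defensible). A caution established during development:
with no population structure at all, the raw inflation of a PC1-as-phenotype
scan is not 1 but approaches the top Marchenko–Pastur eigenvalue
(1 + √(n/m))² of the sample GRM — about 1.3 at n = 100, m = 5,000 — because
the eigenvector is estimated from the very genotypes being tested. The
genomic-control step absorbs this; near-unity raw λ should only be expected
when n/m is small.

**XP-CLR.** The neutral model treats the object-population frequency p₂ as
Gaussian drift around the reference frequency p₁ with variance
ω·p₁(1−p₁), truncated to [0,1] with the truncated tails placed as point
masses at fixation; the observed allele count k of n is binomial given p₂
and integrated numerically (trapezoid, 2,001 points; validated against a
10⁴-point oracle to better than 10⁻⁴). ω is estimated genome-wide by the
method of moments, mean[(p₂−p₁)²/(p₁(1−p₁))]. The sweep model mixes the
neutral density (weight c) with fixation in the direction of p₁ (weight
1−c), where the escape probability is c = 1 − q₀^(r/s̃), r the genetic
distance from the window-center test position under a constant-rate map
(default 1 cM/Mb) and q₀ the beneficial-allele starting frequency
(default 0.005 ≈ 1/(2N) at N = 100). The window statistic is
2·[max over the s̃ grid of the summed log-likelihood difference]. The default
s̃ grid is log-spaced over [10⁻⁵, 10⁻¹] plus a vanishingly small value
(10⁻¹²) so that c ≈ 1 is always attainable and the statistic is
non-negative; distances are floored at half a bp for the same reason. At
most 600 SNPs per window are used (uniform thinning with a recorded seed).
Correlated-SNP down-weighting from the original composite-likelihood design
is deliberately omitted — upstream LD pruning substitutes, and the
simplification keeps the per-SNP likelihood exactly checkable against a
quadrature oracle. SNPs with reference frequency exactly 0 or 1 are excluded
(the neutral variance degenerates).

**Consensus.** Selected windows are merged into regions when their gap is
strictly below 100 kb; merging is idempotent. Consensus is counted at the
gene level: a gene is supported by a method iff it overlaps any merged
region of that method, giving a per-gene support bitmask from which Venn
counts follow.

## Mixed-model GWAS

The kinship matrix is K = ZZᵀ/m on the same standardization as PCA (mean
diagonal ≈ 1 in an outbred cohort). REML estimates the variance-component
ratio δ = σ²_e/σ²_g by spectral decomposition of SKS (S the projector
orthogonal to the covariates), maximizing the restricted likelihood over a
100-point log-spaced grid on [10⁻⁵, 10⁵] followed by bounded scalar
refinement in log δ. Each SNP is then tested by GLS after whitening with
V^(−1/2) at the null fit (the single-fit approximation; with K = I and no
covariates this reduces exactly to per-SNP OLS). Covariates default to the
first five principal components computed on the analysis SNP set. SNPs
collinear with the covariates get missing P. An identity kinship triggers a
non-identifiability warning (δ is then arbitrary).

The effective number of tests follows the eigenvalue rule: within
consecutive 1,000-SNP blocks per chromosome, Mₑ_block =
Σ[1(λᵢ ≥ 1) + (λᵢ − ⌊λᵢ⌋)] over eigenvalues of the dosage correlation
matrix, summed over blocks; monomorphic SNPs carry no test. Thresholds are
suggestive = 1/Mₑ and significant = 0.05/Mₑ. With fewer samples than SNPs
per block, the correlation matrix is rank-deficient and Mₑ is bounded by the
sample count per block — an expected small-n effect, not an error.

## Bulked-segregant analysis

The SNP index is alt/(alt+ref) per bulk with a minimum-depth filter
(default 10 reads); the alt allele is oriented to the cultivated parent, so
a trait-increasing locus appears as Δ > 0 in the high bulk. Windowed means
use the same 100 kb/10 kb grid. The significance band simulates the no-QTL
null: one bulk allele frequency per window per bulk
(Binomial(2m, ½)/2m for bulk size m, default 30/30), shared across the
window's SNPs — within a 100-kb window the bulk's chromosomes are in
essentially perfect linkage, so simulating SNPs independently would shrink
the band — with per-SNP depths resampled from the observed depths and
binomial read counts. 95% and 99% two-sided bands come from 1,000
simulations by default; peaks are maximal runs of windows outside the 99%
band.

Two properties of F2 BSA shape the tests. First, one chromosome is a single
correlated draw of bulk composition (a 65-Mb chromosome at 1 cM/Mb is only
0.65 Morgans), so the fraction of windows outside the band in one
realization does not concentrate near the nominal rate; calibration is
therefore assessed as marginal coverage pooled over many independent
single-window null replicates. Second, near a strong QTL the true Δ curve
plateaus over megabases (recombinants are rare among 60 bulk chromosomes),
so the single highest-|Δ| window is decided by read noise; localization is
asserted as "a 99%-band peak overlapping the QTL attains ≥ 90% of the
maximal Δ", not as the argmax window containing the QTL.

## Downstream analyses

Group allele frequencies and genotype-class counts are simple tabulations.
Multilocus haplotype labels code each locus as "R" (major allele of the
reference wild group; ties at 0.5 resolve to the reference allele) or "A"
(the alternate); heterozygous or missing samples are excluded from labeling
with a reported count, so three loci admit at most 2³ = 8 classes. Trait
group tests are one-way ANOVA plus the two-group rank-sum test
(scipy implementations; these are utilities, not contributions). Trait
correlation screening returns traits with Pearson r strictly above the
cutoff on pairwise-complete observations.

The accession tree is neighbor-joining (scikit-bio) on the 1 − IBS distance,
IBS(i,j) = mean of (2 − |gᵢ−gⱼ|)/2 over shared non-missing SNPs. Samples are
sorted lexicographically before clustering for deterministic tie-breaking;
negative branch lengths are clamped to zero (without redistributing the
deficit to the sister branch — topology, additive-tree exactness and
monophyly checks are unaffected). The distance choice (1 − IBS rather than a
sequence p-distance) is documented here as the package's convention.

## Synthetic cohorts

The generator produces exactly the statistical structure the scans consume,
at negligible cost, via the Balding–Nichols model: ancestral frequencies
uniform on (0.05, 0.95), population frequencies Beta-distributed around them
with drift parameter F (default 0.1 per population), and F_sweep (default
0.9) replacing F for the cultivated group inside designated sweep regions.
Defaults mirror the reference cohort at desk scale: 53 + 166 samples, two
5-Mb chromosomes, 10,000 SNPs, three 300-kb sweeps. No linkage
disequilibrium is simulated between sites — a documented limitation: the
r-dependence of the XP-CLR sweep model is therefore exercised through the F2
simulator (real recombination under a Haldane map), not through the cohort
generator, and LD-dependent behavior (pruning, effective-test counts) is
tested on constructed genotypes. Consequently, passing recovery tests show
the scans respond correctly to frequency differentiation and diversity
collapse; they do not validate haplotype-structure signals.

Phenotypes are built from components standardized to exact empirical
variance fractions: named QTL effects (β ∝ √fraction), a polygenic term
Zw/√m with kinship covariance, and residual noise filling the remainder.
The F2 simulator crosses two fully homozygous, fully divergent parents,
recombines gametes as a Poisson process on the genetic map (default
1 cM/Mb), assigns phenotype = QTL effect + noise, takes the phenotype tails
as bulks (default 30/30 of 500), and draws reads as
Binomial(Poisson(depth), bulk frequency) at mean depth 30. The default F2
chromosome is 65 Mb with the QTL at 63.4 Mb, matching the scale of the real
mapping target; a few-Mb toy chromosome carries almost no recombination and
cannot localize anything.

All generators are pure functions of (scenario, seed).

## Problem sizes and numerical choices

Test and acceptance runs use the desk-scale defaults above (10⁴ SNPs,
~10³ windows, n ≤ 300 for GWAS, 400 replicates for BSA calibration), chosen
so the whole suite completes in a few minutes while leaving every statistic
well inside its asymptotic regime. Quadrature uses 2,001 trapezoid points;
REML tolerances are 10⁻¹⁰ in log δ; eigenvalues are clipped at 0 before
square roots; likelihoods are floored at 10⁻³⁰⁰ before logs. Degenerate
inputs (empty windows, monomorphic SNPs, all-zero diversity, identity
kinship) return missing values, warnings or documented exclusions rather
than raising, except where the spec of an operation is genuinely violated
(negative counts, mismatched grids, insufficient samples).

## Known limitations

* No phasing, imputation, indel or multiallelic support.
* XP-CLR omits correlated-SNP down-weighting (see above) and uses a constant
  recombination map.
* The cohort generator has no LD; sweep regions are frequency-coupled only.
* No bootstrap support on trees; no G′ statistic for BSA; empirical
  quantiles only (no sweep significance testing), matching the pipeline's
  design.
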