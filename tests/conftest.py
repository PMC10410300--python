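import numpy as np
import pandas as pd
import pytest

from sweepscan import GenotypeMatrix, GroupAssignment, SimScenario, simulate_divergence


def make_gm(dosage, chrom="chr1", positions=None, samples=None):
    """Build a GenotypeMatrix from a (samples x variants) dosage array."""
    dosage = np.asarray(dosage, dtype=np.int16)
    n, m = dosage.shape
    if positions is None:
        positions = np.arange(m) * 100
    if samples is None:
        samples = [f"S{i:02d}" for i in range(n)]
    variants = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "G"}
    )
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


@pytest.fixture(scope="session")
def small_cohort():
    """20 + 40 sample two-population cohort with one planted sweep."""
    from sweepscan import GenomicRegion

    scn = SimScenario(
        n_pim=20,
        n_big=40,
        chrom_lengths={"chr1": 1_000_000},
        n_snps=1500,
        sweeps=[GenomicRegion("chr1", 300_000, 500_000)],
        seed=9,
    )
    gm, groups, truth = simulate_divergence(scn)
    return gm, groups, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
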