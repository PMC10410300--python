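"""Windowed diversity, the three selection scans, empirical thresholds,
region merging and the gene-level consensus."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sweepscan import (
    GenomicRegion,
    GroupAssignment,
    SweepModel,
    eigengwas_scan,
    empirical_threshold,
    estimate_omega,
    make_windows,
    merge_regions,
    pca_eigenvectors,
    pi_ratio_scan,
    sweep_consensus,
    windowed_pi,
)
from sweepscan.genodata import MISSING, GeneModel
from sweepscan.selscan import (
    genomic_control,
    neutral_likelihood,
    site_pi,
    snp_regression,
    sweep_likelihood,
)

from conftest import make_gm


def groups_all(gm, label="G"):
    return GroupAssignment(pd.Series(label, index=gm.samples, dtype=str))


def brute_force_pi(dosage):
    """Mean pairwise allele difference per site over haplotype-expanded data."""
    out = []
    for j in range(dosage.shape[1]):
        alleles = []
        for d in dosage[:, j]:
            if d == MISSING:
                continue
            alleles += [1] * int(d) + [0] * (2 - int(d))
        n = len(alleles)
        if n < 2:
            out.append(0.0)
            continue
        diff = sum(
            alleles[a] != alleles[b] for a in range(n) for b in range(a + 1, n)
        )
        out.append(diff / (n * (n - 1) / 2))
    return np.array(out)


class TestWindowedPi:
    def test_single_site_worked_example(self):
        # 2 diploids -> 4 alleles, 2 alt: 4 differing of 6 pairs = 2/3
        gm = make_gm([[1], [1]], positions=[10])
        grid = make_windows({"chr1": 100}, 100, 100)
        g = groups_all(gm)
        pi = windowed_pi(gm, "G", g, grid)
        assert pi[0] == pytest.approx((2 / 3) / 100)

    def test_monomorphic_window_zero(self):
        gm = make_gm([[0], [0], [0]], positions=[10])
        pi = windowed_pi(gm, "G", groups_all(gm), make_windows({"chr1": 100}, 100, 100))
        assert pi[0] == 0.0

    def test_matches_pairwise_difference_oracle(self, rng):
        for _ in range(10):
            dosage = rng.integers(0, 3, size=(8, 10)).astype(np.int16)
            dosage[rng.random(dosage.shape) < 0.1] = MISSING
            gm = make_gm(dosage, positions=np.arange(10) * 7 + 3)
            grid = make_windows({"chr1": 100}, 100, 100)
            pi = windowed_pi(gm, "G", groups_all(gm), grid)
            expect = brute_force_pi(dosage).sum() / 100
            assert pi[0] == pytest.approx(expect, abs=1e-12)

    def test_invariant_to_sample_order_and_allele_swap(self, rng):
        dosage = rng.integers(0, 3, size=(6, 20)).astype(np.int16)
        gm = make_gm(dosage)
        grid = make_windows({"chr1": 2000}, 2000, 2000)
        base = windowed_pi(gm, "G", groups_all(gm), grid)
        perm = rng.permutation(6)
        shuffled = make_gm(dosage[perm])
        swapped = make_gm(2 - dosage)
        assert windowed_pi(shuffled, "G", groups_all(shuffled), grid) == pytest.approx(base)
        assert windowed_pi(swapped, "G", groups_all(swapped), grid) == pytest.approx(base)
        assert np.all(base >= 0)


class TestPiRatio:
    def test_ratio_arithmetic_and_infinite_rule(self):
        grid = make_windows({"chr1": 30_000}, 10_000, 10_000)
        res = pi_ratio_scan(
            np.array([0.01, 0.004, 0.0]), np.array([0.001, 0.0, 0.0]), grid
        )
        stat = res.table["stat"]
        assert stat[0] == pytest.approx(10.0)
        assert np.isposinf(stat[1])  # obj zero, ref positive -> top rank
        assert np.isnan(stat[2])  # both zero -> excluded
        assert res.table.loc[1, "selected"]

    def test_top_five_percent_matches_sort_oracle(self, rng):
        grid = make_windows({"chr1": 100 * 1000}, 1000, 1000)
        ref = rng.uniform(0.001, 0.02, 100)
        obj = rng.uniform(0.001, 0.02, 100)
        res = pi_ratio_scan(ref, obj, grid)
        ratio = ref / obj
        expect = set(np.argsort(ratio)[-5:])
        assert set(np.flatnonzero(res.table["selected"])) == expect

    def test_grid_mismatch_errors(self):
        grid = make_windows({"chr1": 20_000}, 10_000, 10_000)
        with pytest.raises(ValueError):
            pi_ratio_scan(np.ones(3), np.ones(2), grid)


class TestPca:
    def test_two_groups_separate_on_ev1(self, small_cohort):
        gm, groups, _ = small_cohort
        ev, vals = pca_eigenvectors(gm, 2)
        pim = groups.sample_idx(gm, "PIM")
        big = groups.sample_idx(gm, "BIG")
        assert abs(ev[pim, 0].mean() - ev[big, 0].mean()) > 5 * ev[:, 0].std() / 4
        # sign rule: largest-magnitude entry positive
        assert ev[np.argmax(np.abs(ev[:, 0])), 0] > 0

    def test_single_variant_closed_form(self):
        gm = make_gm([[0], [1], [2], [1]])
        ev, vals = pca_eigenvectors(gm, 1)
        d = gm.dosage[:, 0].astype(float)
        z = (d - d.mean()) / np.sqrt(2 * 0.5 * 0.5)
        expect = z / np.linalg.norm(z)
        assert np.allclose(np.abs(ev[:, 0]), np.abs(expect))

    def test_eigenvalue_sum_equals_trace(self, small_cohort):
        gm, _, _ = small_cohort
        ev, vals = pca_eigenvectors(gm, gm.n_samples)
        from sweepscan.selscan import standardized_dosage

        Z, poly = standardized_dosage(gm)
        G = Z @ Z.T / poly.sum()
        assert vals.sum() == pytest.approx(np.trace(G), rel=1e-8)

    def test_k_above_n_errors(self, small_cohort):
        gm, _, _ = small_cohort
        with pytest.raises(ValueError):
            pca_eigenvectors(gm, gm.n_samples + 1)


class TestEigenGwas:
    def test_orthogonal_phenotype_gives_null_test(self):
        gm = make_gm([[0], [2], [0], [2]])
        y = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal to centered dosage
        res = snp_regression(y, gm)
        assert res["beta"][0] == pytest.approx(0.0, abs=1e-12)
        assert res["p"][0] == pytest.approx(1.0)

    def test_lambda_identity_when_median_matches_null(self):
        chisq = np.full(99, 0.4549364231195724)
        lam, adj = genomic_control(chisq)
        assert lam == pytest.approx(1.0)
        assert adj == pytest.approx(chisq)

    def test_beta_se_match_closed_form_ols(self, rng):
        dosage = rng.integers(0, 3, size=(6, 1)).astype(np.int16)
        gm = make_gm(dosage)
        y = rng.normal(size=6)
        res = snp_regression(y, gm)
        x = dosage[:, 0].astype(float)
        xc, yc = x - x.mean(), y - y.mean()
        b = (xc @ yc) / (xc @ xc)
        resid = yc - b * xc
        se = np.sqrt(resid @ resid / 4 / (xc @ xc))
        assert res["beta"][0] == pytest.approx(b, rel=1e-10)
        assert res["se"][0] == pytest.approx(se, rel=1e-10)

    def test_lambda_near_one_without_structure(self):
        # raw inflation approaches the top Marchenko-Pastur eigenvalue
        # (1 + sqrt(n/m))^2, so near-calibration needs n/m small
        from sweepscan import SimScenario, simulate_divergence

        scn = SimScenario(
            n_pim=0,
            n_big=100,
            n_snps=40_000,
            f_big=0.05,
            f_pim=0.05,
            f_sweep=0.5,
            chrom_lengths={"chr1": 8_000_000},
            sweeps=[],
        )
        gm, groups, _ = simulate_divergence(scn, seed=21)
        grid = make_windows(scn.chrom_lengths, 100_000, 100_000)
        ev, _ = pca_eigenvectors(gm, 1)
        res = eigengwas_scan(gm, ev[:, 0], grid)
        assert 0.8 <= res.meta["lambda_gc"] <= 1.2


class TestOmega:
    def test_zero_when_frequencies_identical(self):
        p = np.array([0.2, 0.5, 0.8])
        assert estimate_omega(p, p).omega == 0.0

    def test_linear_in_squared_deviation(self):
        p_ref = np.array([0.5, 0.5])
        base = estimate_omega(p_ref, np.array([0.6, 0.4])).omega
        doubled = estimate_omega(p_ref, np.array([0.5 + 0.1 * np.sqrt(2), 0.5 - 0.1 * np.sqrt(2)])).omega
        assert doubled == pytest.approx(2 * base)

    def test_recovers_drift_parameter_of_simulated_frequencies(self, rng):
        F = 0.1
        p = rng.uniform(0.1, 0.9, size=10_000)
        p_obj = rng.beta(p * (1 - F) / F, (1 - p) * (1 - F) / F)
        assert estimate_omega(p, p_obj).omega == pytest.approx(F, abs=0.01)

    def test_errors_without_polymorphic_reference(self):
        with pytest.raises(ValueError):
            estimate_omega(np.array([0.0, 1.0]), np.array([0.1, 0.9]))


class TestXpclrModel:
    def test_neutral_likelihood_matches_dense_quadrature(self, rng):
        for _ in range(10):
            k = float(rng.integers(0, 21))
            n = 20.0
            p1 = float(rng.uniform(0.05, 0.95))
            om = float(rng.uniform(0.05, 0.5))
            mine = neutral_likelihood(k, n, p1, om)[0]
            x = np.linspace(0, 1, 10_001)
            sig = np.sqrt(om * p1 * (1 - p1))
            integ = np.trapezoid(
                stats.binom.pmf(int(k), int(n), np.clip(x, 1e-12, 1 - 1e-12))
                * stats.norm.pdf(x, p1, sig),
                x,
            )
            oracle = integ + stats.norm.cdf(0, p1, sig) * (k == 0) + stats.norm.sf(
                1, p1, sig
            ) * (k == n)
            assert mine == pytest.approx(oracle, abs=1e-4)

    def test_escape_probability_arithmetic(self):
        sw = SweepModel(s_grid=(1.0,), q0=0.5)
        assert sw.escape_prob(0.0)[0, 0] == 0.0  # r = 0 -> dragged to fixation
        assert sw.escape_prob(1.0)[0, 0] == pytest.approx(0.5)  # q0=0.5, r/s=1

    def test_sweep_model_reduces_to_neutral_at_large_distance(self):
        ln = neutral_likelihood(np.array([5.0]), np.array([20.0]), np.array([0.4]), 0.2)
        sw = SweepModel(s_grid=(1e-6,), q0=0.005)
        c = sw.escape_prob(np.array([1.0]))  # r/s huge -> c ~ 1
        ls = sweep_likelihood(ln, c[0], np.array([5.0]), np.array([20.0]), np.array([0.4]))
        assert np.log(ls[0]) - np.log(ln[0]) == pytest.approx(0.0, abs=1e-9)


class TestEmpiricalThreshold:
    def test_interpolated_quantile_of_integer_grid(self):
        stats_ = np.arange(1, 101, dtype=float)
        thr = empirical_threshold(stats_, 0.05)
        assert thr == pytest.approx(95.05)
        assert (stats_ >= thr).sum() == 5

    def test_ties_at_threshold_selected(self):
        thr = empirical_threshold(np.full(10, 3.0), 0.05)
        assert np.all(np.full(10, 3.0) >= thr)

    def test_infinite_value_always_selected(self):
        v = np.array([1.0, 2.0, 3.0, np.inf])
        thr = empirical_threshold(v, 0.25)
        assert np.inf >= thr

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            empirical_threshold(np.array([np.nan]), 0.05)


class TestMergeRegions:
    def test_gap_below_100kb_merges(self):
        regs = [GenomicRegion("chr1", 0, 200_000), GenomicRegion("chr1", 250_000, 300_000)]
        assert merge_regions(regs, 100_000) == [GenomicRegion("chr1", 0, 300_000)]

    def test_gap_exactly_100kb_not_merged(self):
        regs = [GenomicRegion("chr1", 0, 200_000), GenomicRegion("chr1", 300_000, 400_000)]
        assert len(merge_regions(regs, 100_000)) == 2

    def test_matches_fixpoint_pairwise_oracle(self, rng):
        regs = [
            GenomicRegion("chr1", int(s), int(s) + int(l))
            for s, l in zip(
                rng.integers(0, 5000, 30), rng.integers(10, 500, 30)
            )
        ]
        merged = merge_regions(regs, 100)
        # fixpoint: merging again changes nothing
        assert merge_regions(merged, 100) == merged
        # oracle: exhaustive pairwise merge to fixpoint
        pool = [[r.start, r.end] for r in regs]
        changed = True
        while changed:
            changed = False
            for i in range(len(pool)):
                for j in range(i + 1, len(pool)):
                    a, b = pool[i], pool[j]
                    if a and b and max(a[0], b[0]) - min(a[1], b[1]) < 100:
                        a[0], a[1] = min(a[0], b[0]), max(a[1], b[1])
                        pool[j] = []
                        changed = True
            pool = [p for p in pool if p]
        assert sorted((p[0], p[1]) for p in pool) == [
            (r.start, r.end) for r in merged
        ]
        # output sorted, non-overlapping, gaps >= max_gap
        for a, b in zip(merged, merged[1:]):
            assert b.start - a.end >= 100


class TestConsensus:
    def test_gene_supported_by_all_methods(self):
        genes = [GeneModel("g1", "chr1", 100, 200)]
        regs = {m: [GenomicRegion("chr1", 0, 500)] for m in ("a", "b", "c")}
        tab = sweep_consensus(regs, genes)
        assert tab.loc[0, "bitmask"] == "111"

    def test_disjoint_methods_have_empty_intersection(self):
        genes = [GeneModel("g1", "chr1", 100, 200), GeneModel("g2", "chr1", 900, 950)]
        regs = {
            "a": [GenomicRegion("chr1", 0, 500)],
            "b": [GenomicRegion("chr1", 600, 1000)],
        }
        tab = sweep_consensus(regs, genes)
        assert (tab["n_methods"] == 2).sum() == 0

    def test_venn_counts_match_membership_oracle(self, rng):
        genes = [
            GeneModel(f"g{i}", "chr1", int(p), int(p) + 30)
            for i, p in enumerate(rng.integers(0, 2000, 20))
        ]
        regs = {
            "a": [GenomicRegion("chr1", 0, 700)],
            "b": [GenomicRegion("chr1", 500, 1200)],
            "c": [GenomicRegion("chr1", 1000, 2000)],
        }
        tab = sweep_consensus(regs, genes).set_index("gene_id")
        for g in genes:
            for m, rlist in regs.items():
                member = any(
                    g.start < r.end and r.start < g.end for r in rlist
                )
                if g.gene_id in tab.index:
                    assert bool(tab.loc[g.gene_id, m]) == member
                else:
                    assert not member
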