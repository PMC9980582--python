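"""Quasi-binomial LRT, BH adjustment and the dual DMC filter."""

import numpy as np
import pytest
from scipy import optimize, special, stats

from methclash import Dataset, SimulationConfig, run_pipeline, simulate_dataset
from methclash.coverage_matrix import build_matrix, merge_seasons
from methclash.diff_methylation import bh_adjust, call_dmcs, classify_diff
from methclash.diff_methylation import test_site as site_test
from methclash.io_formats import DataError, MethylationCall, SampleInfo


class TestTestSite:
    def test_maximal_separation(self):
        p, diff = site_test([10] * 5, [0] * 5, [0] * 5, [10] * 5)
        assert diff == pytest.approx(1.0)
        assert p < 1e-4

    def test_null_identity(self):
        counts = ([7, 8, 6], [3, 2, 4])
        p, diff = site_test(*counts, *counts)
        assert diff == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_against_numerical_likelihood_maximization(self):
        # independent oracle: maximize each binomial likelihood numerically,
        # then push the LRT through the same dispersion/F reference
        m1, u1 = [7, 8, 6, 7, 7], [3, 2, 4, 3, 3]
        m2, u2 = [3, 2, 4, 3, 3], [7, 8, 6, 7, 7]

        def negll(p, m, u):
            return -(special.xlogy(sum(m), p) + special.xlogy(sum(u), 1 - p))

        def mle(m, u):
            return optimize.minimize_scalar(
                negll, bounds=(1e-9, 1 - 1e-9), args=(m, u), method="bounded").x

        p1, p2 = mle(m1, u1), mle(m2, u2)
        p0 = mle(m1 + m2, u1 + u2)
        lrt = 2 * (negll(p0, m1 + m2, u1 + u2)
                   - negll(p1, m1, u1) - negll(p2, m2, u2))
        x2 = sum((m - (m + u) * ph) ** 2 / ((m + u) * ph * (1 - ph))
                 for ph, ms, us in ((p1, m1, u1), (p2, m2, u2))
                 for m, u in zip(ms, us))
        phi = max(x2 / 8, 1.0)
        expected_p = stats.f.sf(lrt / phi, 1, 8)

        p, diff = site_test(m1, u1, m2, u2)
        assert p == pytest.approx(expected_p, rel=0.10)
        assert diff == pytest.approx(0.4)

    def test_requires_two_covered_samples_per_group(self):
        with pytest.raises(DataError):
            site_test([5, 0], [5, 0], [5, 5], [5, 5])

    def test_pooled_vs_mean_of_fractions_diff(self):
        # unbalanced coverage: unweighted mean resists the deep sample
        m1, u1 = [90, 1], [10, 9]
        m2, u2 = [5, 5], [5, 5]
        _, d_mean = site_test(m1, u1, m2, u2, diff_mode="mean_of_fractions")
        _, d_pool = site_test(m1, u1, m2, u2, diff_mode="pooled")
        assert d_mean == pytest.approx(abs((0.9 + 0.1) / 2 - 0.5))
        assert d_pool == pytest.approx(abs(91 / 110 - 0.5))


class TestBhAdjust:
    def _step_up(self, p):
        # hand BH: p(i) * m / i with cumulative min from the largest rank
        p = np.asarray(p, dtype=float)
        order = np.argsort(p)
        m = len(p)
        adj = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(adj, 1.0)
        return out

    @pytest.mark.parametrize("pvals,expected", [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([1.0], [1.0]),
        ([0.05] * 100, [0.05] * 100),
    ])
    def test_known_values(self, pvals, expected):
        assert bh_adjust(pvals) == pytest.approx(expected)

    def test_matches_hand_step_up_on_random_input(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=500)
        assert np.allclose(bh_adjust(p), self._step_up(p), rtol=1e-10)

    def test_empty_and_invalid(self):
        assert bh_adjust([]).size == 0
        with pytest.raises(DataError):
            bh_adjust([0.5, 1.5])


def _matrix_from_counts(M, U, groups):
    samples = [SampleInfo(f"S{j}", f"S{j}", g, "C") for j, g in enumerate(groups)]
    calls = {
        s.sample_id: [MethylationCall("chr1", 10 * (i + 1), "+",
                                      int(M[i, j]), int(U[i, j]))
                      for i in range(M.shape[0])]
        for j, s in enumerate(samples)
    }
    return build_matrix(calls, samples, min_cov=0)


class TestCallDmcs:
    def test_impossible_min_diff_yields_no_dmcs(self):
        M = np.array([[10, 10, 0, 0]] * 3)
        U = 10 - M
        mat = _matrix_from_counts(M, U, ["A", "A", "N", "N"])
        records, summary = call_dmcs(mat, min_diff=1.1)
        assert summary.n_dmc == 0
        assert all(not r.is_dmc for r in records)

    def test_dual_filter_decomposition(self):
        # a site failing either filter alone must never be a DMC
        cfg = SimulationConfig(n_cpg_sites=400, n_true_dmc=40, n_fixed_snps=20,
                               n_segregating_snps=20, cluster_geometry=(2, 4, 400),
                               n_genes=5, seed=21)
        ds = simulate_dataset(cfg)
        mat = merge_seasons(build_matrix(ds.calls, ds.samples, min_cov=0), 10)
        records, _ = call_dmcs(mat, fdr=0.05, min_diff=0.10)
        for r in records:
            assert r.is_dmc == (r.q_value <= 0.05 and r.abs_meth_diff >= 0.10)
            assert (r.diff_class != "none") == r.is_dmc

    def test_class_partition_sums_to_dmc_count(self, small_result):
        summary = small_result.dmc_summary
        assert sum(summary.class_counts.values()) == summary.n_dmc
        for r in small_result.dmc_records:
            if r.is_dmc:
                assert r.diff_class == classify_diff(r.abs_meth_diff)

    def test_null_simulation_controls_fdr(self):
        cfg = SimulationConfig(n_cpg_sites=3000, n_true_dmc=0, breed_effect_sd=0.0,
                               n_fixed_snps=0, n_segregating_snps=0,
                               cluster_geometry=(0, 0, 500), n_genes=5, seed=33)
        ds = simulate_dataset(cfg)
        mat = merge_seasons(build_matrix(ds.calls, ds.samples, min_cov=0), 10)
        _, summary = call_dmcs(mat)
        assert summary.n_tested >= 2000
        assert summary.n_dmc / summary.n_tested <= 0.06

    def test_power_on_large_effects(self):
        cfg = SimulationConfig(n_cpg_sites=1500, n_true_dmc=150,
                               effect_classes={"gt70": 1.0},
                               n_fixed_snps=0, n_segregating_snps=0,
                               cluster_geometry=(0, 0, 500), n_genes=5, seed=17)
        ds = simulate_dataset(cfg)
        mat = merge_seasons(build_matrix(ds.calls, ds.samples, min_cov=0), 10)
        records, _ = call_dmcs(mat)
        truth = ds.truth.true_dmc_sites()
        called = {(r.chrom, r.pos) for r in records if r.is_dmc}
        tested = {(r.chrom, r.pos) for r in records}
        detectable = truth & tested
        assert len(detectable) > 100
        sensitivity = len(detectable & called) / len(detectable)
        assert sensitivity >= 0.95

    def test_fisher_mode_agrees_on_extreme_sites(self):
        M = np.array([[10, 10, 0, 0], [5, 5, 5, 5]])
        U = 10 - M
        mat = _matrix_from_counts(M, U, ["A", "A", "N", "N"])
        rq, _ = call_dmcs(mat, test="qlrt")
        rf, _ = call_dmcs(mat, test="fisher")
        assert rf[0].p_value < 1e-4 and rq[0].p_value < 0.05
        assert rf[1].abs_meth_diff == rq[1].abs_meth_diff == 0
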