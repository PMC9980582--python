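"""Generator contracts: determinism, truth bookkeeping, calibration."""

import numpy as np
import pytest

from methclash.io_formats import ConfigurationError
from methclash.pipeline import load_dataset_dir
from methclash.synthetic_data import (
    SimulationConfig,
    generate_truth,
    simulate_counts,
    simulate_dataset,
    write_dataset,
)


def _cfg(**kw):
    base = dict(n_cpg_sites=500, n_fixed_snps=40, n_segregating_snps=40,
                n_true_dmc=40, cluster_geometry=(3, 5, 400), n_genes=10, seed=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestGenerateTruth:
    def test_same_seed_identical_truth(self):
        a = generate_truth(_cfg())
        b = generate_truth(_cfg())
        assert a.sites.equals(b.sites)
        assert a.snps.equals(b.snps)
        assert [g for g in a.genes] == [g for g in b.genes]

    def test_different_seed_differs(self):
        a = generate_truth(_cfg(seed=1))
        b = generate_truth(_cfg(seed=2))
        assert not a.sites.pos.equals(b.sites.pos)

    def test_no_true_dmc_means_no_effects(self):
        truth = generate_truth(_cfg(n_true_dmc=0))
        assert (truth.sites.group_effect == 0).all()
        assert (truth.sites.cluster_id == -1).all()

    def test_confound_count_is_exact(self):
        truth = generate_truth(_cfg(frac_csnp_confound=1.0, n_fixed_snps=10))
        assert int(truth.sites.is_csnp_confounded.sum()) == 10
        # every confounded site is a C->T fixed SNP on a CpG position
        conf = truth.confounded_sites()
        fixed_ct = {(r.chrom, r.pos) for r in truth.snp_records
                    if r.ref_allele == "C" and r.alt_alleles == ("T",)}
        assert conf <= fixed_ct

    def test_confounded_sites_carry_no_true_effect(self):
        truth = generate_truth(_cfg(frac_csnp_confound=0.5))
        conf = truth.sites[truth.sites.is_csnp_confounded]
        assert (conf.group_effect == 0).all()

    def test_all_gt70_class(self):
        truth = generate_truth(_cfg(effect_classes={"gt70": 1.0}))
        eff = truth.sites.group_effect
        assert (eff[eff != 0].abs() > 0.70).all()

    def test_effect_floor_respected(self):
        truth = generate_truth(_cfg())
        eff = truth.sites.group_effect
        assert (eff[eff != 0].abs() >= 0.10).all()

    def test_cluster_geometry(self):
        truth = generate_truth(_cfg())
        for cid, members in truth.true_clusters().items():
            assert len(members) == 5
            assert members.chrom.nunique() == 1
            gaps = np.diff(np.sort(members.pos.to_numpy()))
            assert (gaps < 400).all()
            signs = np.sign(members.group_effect.to_numpy())
            assert len(set(signs)) == 1

    def test_capacity_validation(self):
        with pytest.raises(ConfigurationError):
            generate_truth(_cfg(genome=(("chr1", 600),)))

    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            _cfg(effect_classes={"lt30": 0.5}).validate()


class TestSimulateCounts:
    def test_determinism_byte_identical(self, tmp_path):
        d1 = tmp_path / "a"
        d2 = tmp_path / "b"
        write_dataset(simulate_dataset(_cfg(seed=4)), d1)
        write_dataset(simulate_dataset(_cfg(seed=4)), d2)
        for p1 in sorted(d1.iterdir()):
            assert p1.read_bytes() == (d2 / p1.name).read_bytes()

    def test_binomial_mean_recovered(self):
        # no effects of any kind: pooled mean fraction estimates baseline
        cfg = _cfg(n_cpg_sites=2000, n_true_dmc=0, breed_effect_sd=0.0,
                   individual_effect_sd=0.0, season_effect_sd=0.0,
                   cluster_geometry=(0, 0, 400), frac_csnp_confound=0.0,
                   n_fixed_snps=0, n_segregating_snps=0)
        ds = simulate_dataset(cfg)
        truth = ds.truth
        m = u = 0
        for calls in ds.calls.values():
            m += sum(c.n_meth for c in calls)
            u += sum(c.n_unmeth for c in calls)
        # binomial mean: E[m/(m+u)] -> mean baseline (coverage independent
        # of baseline); SE at this scale << 0.01
        assert m / (m + u) == pytest.approx(truth.sites.baseline.mean(), abs=0.01)

    def test_marginal_calibration_to_beta_mean(self):
        cfg = _cfg(n_cpg_sites=10_000, n_true_dmc=0, frac_csnp_confound=0.0,
                   n_fixed_snps=0, n_segregating_snps=0,
                   cluster_geometry=(0, 0, 400),
                   genome=(("chr1", 2_000_000), ("chr2", 2_000_000)))
        ds = simulate_dataset(cfg)
        a, b = cfg.methylation_beta_params
        m = u = 0
        for calls in ds.calls.values():
            m += sum(c.n_meth for c in calls)
            u += sum(c.n_unmeth for c in calls)
        assert m / (m + u) == pytest.approx(a / (a + b), abs=0.02)

    def test_confounded_group_reads_fully_unmethylated(self):
        cfg = _cfg(frac_csnp_confound=1.0, n_fixed_snps=5)
        ds = simulate_dataset(cfg)
        truth = ds.truth
        conf = truth.sites[truth.sites.is_csnp_confounded]
        for _, row in conf.iterrows():
            tt_group = row.csnp_alt_group
            for s in ds.samples:
                call = next(c for c in ds.calls[s.sample_id]
                            if (c.chrom, c.pos) == (row.chrom, row.pos))
                if s.group == tt_group:
                    assert call.n_meth == 0

    def test_season_replicates_share_individual_effects(self):
        # with only individual effects, an animal's two seasons correlate
        # far more than two animals within a season
        cfg = _cfg(n_cpg_sites=2000, n_true_dmc=0, breed_effect_sd=0.0,
                   individual_effect_sd=0.15, season_effect_sd=0.0,
                   cluster_geometry=(0, 0, 400), frac_csnp_confound=0.0,
                   n_fixed_snps=0, n_segregating_snps=0)
        ds = simulate_dataset(cfg)

        def frac(sample_id):
            return np.array([c.n_meth / max(c.coverage, 1)
                             for c in ds.calls[sample_id]])

        within = np.corrcoef(frac("A1_C"), frac("A1_R"))[0, 1]
        between = np.corrcoef(frac("A1_C"), frac("A2_C"))[0, 1]
        assert within > between + 0.1

    def test_write_then_load_round_trip(self, tmp_path, small_dataset):
        write_dataset(small_dataset, tmp_path)
        loaded = load_dataset_dir(tmp_path)
        sid = small_dataset.samples[0].sample_id
        assert loaded.calls[sid] == sorted(
            small_dataset.calls[sid], key=lambda c: (c.chrom, c.pos))
        assert len(loaded.snps) == len(small_dataset.snps)
        assert loaded.genes == sorted(
            small_dataset.genes, key=lambda g: (g.chrom, g.start))
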