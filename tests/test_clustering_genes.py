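"""Stretch clustering, gene assignment, density ranking, set enrichment."""

import math
import random

import pytest

from methclash.clustering_genes import (
    GeneDmcSummary,
    assign_genes,
    cluster_stretches,
    geneset_enrichment,
    group_by_cluster_size,
    rank_by_density,
    read_gmt,
)
from methclash.io_formats import DataError, DmcRecord, GeneAnnotation


def _dmc(pos, sign=1, chrom="chr1"):
    g1 = 0.8 if sign > 0 else 0.2
    return DmcRecord(chrom, pos, "+", g1, 1 - g1, abs(2 * g1 - 1),
                     1e-6, 1e-5, True, "30to70")


def _gene(start, end, strand="+", gene_id="G1", chrom="chr1"):
    return GeneAnnotation(chrom, start, end, strand, gene_id)


class TestClusterStretches:
    def test_gap_rule_and_singletons(self):
        clusters = cluster_stretches([_dmc(100), _dmc(900), _dmc(5000)],
                                     max_gap=2000)
        assert len(clusters) == 1
        assert clusters[0].positions == (100, 900)  # 5000 stays a singleton

    def test_direction_flag(self):
        dmcs = [_dmc(100, +1), _dmc(200, -1)]
        assert cluster_stretches(dmcs, require_same_direction=True) == []
        (c,) = cluster_stretches(dmcs, require_same_direction=False)
        assert c.size == 2

    def test_long_stretch_stays_single(self):
        # structural analogue of a ~305-CpG run with sub-threshold gaps
        dmcs = [_dmc(1000 + 50 * i) for i in range(305)]
        (c,) = cluster_stretches(dmcs, max_gap=2000)
        assert c.size == 305
        assert c.max_internal_gap < 2000

    def test_input_order_invariance(self):
        dmcs = [_dmc(p) for p in (100, 900, 5000, 5100)]
        shuffled = dmcs[:]
        random.Random(0).shuffle(shuffled)
        assert cluster_stretches(dmcs) == cluster_stretches(shuffled)

    def test_chromosome_break(self):
        dmcs = [_dmc(100), _dmc(300, chrom="chr2"), _dmc(500, chrom="chr2")]
        (c,) = cluster_stretches(dmcs)
        assert c.chrom == "chr2" and c.positions == (300, 500)


class TestAssignGenes:
    def test_promoter_flank_strand_aware(self):
        gene = _gene(1000, 2000, "+")
        (s,) = assign_genes([_dmc(500)], [], [gene], promoter_flank=2000)
        assert s.n_dmc == 1  # 500 is upstream of the + gene within the flank
        assert assign_genes([_dmc(2001)], [], [gene], promoter_flank=2000) == []
        minus = _gene(1000, 2000, "-")
        (s,) = assign_genes([_dmc(2001)], [], [minus], promoter_flank=2000)
        assert s.n_dmc == 1

    def test_zero_flank_restricts_to_gene_body(self):
        gene = _gene(1000, 2000, "+")
        assert assign_genes([_dmc(999)], [], [gene], promoter_flank=0) == []
        (s,) = assign_genes([_dmc(1000)], [], [gene], promoter_flank=0)
        assert s.n_dmc == 1

    def test_overlapping_genes_share_dmcs(self):
        genes = [_gene(100, 1000, gene_id="A"), _gene(500, 1500, gene_id="B")]
        out = assign_genes([_dmc(700)], [], genes, promoter_flank=0)
        assert {s.gene_id for s in out} == {"A", "B"}

    def test_cluster_attached_through_any_member(self):
        dmcs = [_dmc(900), _dmc(1100)]
        (cluster,) = cluster_stretches(dmcs, max_gap=2000)
        gene = _gene(1000, 2000, "+")
        (s,) = assign_genes(dmcs, [cluster], [gene], promoter_flank=0)
        assert s.largest_cluster_size == 2 and s.cluster_count == 1


class TestRankingAndGrouping:
    def _summary(self, gene_id, n_dmc, length, largest=0, count=0):
        return GeneDmcSummary(gene_id, "chr1", 1, length, "+", length,
                              n_dmc, largest, count)

    def test_density_ranking(self):
        a = self._summary("A", 10, 1000)
        b = self._summary("B", 10, 10_000)
        assert rank_by_density([b, a])[0].gene_id == "A"

    def test_tie_broken_lexicographically(self):
        a = self._summary("A", 5, 1000)
        b = self._summary("B", 5, 1000)
        assert [s.gene_id for s in rank_by_density([b, a])] == ["A", "B"]

    def test_empty_input(self):
        assert rank_by_density([]) == []

    def test_grouping_counts_and_percentages(self):
        summaries = (
            [self._summary(f"G{i}", 4, 1000, largest=4) for i in range(600)]
            + [self._summary(f"H{i}", 3, 1000, largest=3) for i in range(321)]
            + [self._summary(f"I{i}", 2, 1000, largest=2) for i in range(956)]
            + [self._summary(f"J{i}", 1, 1000, largest=0) for i in range(100)]
        )
        out = group_by_cluster_size(summaries, total_dmg_count=5742)
        assert out["counts"] == {"ge2": 1877, "ge3": 921, "gt3": 600}
        assert out["percentages"] == {"ge2": 32.7, "ge3": 16.0, "gt3": 10.4}

    def test_grouping_edge_cases(self):
        singles = [self._summary("A", 1, 1000, largest=0)]
        out = group_by_cluster_size(singles)
        assert out["counts"] == {"ge2": 0, "ge3": 0, "gt3": 0}
        one = [self._summary("A", 4, 1000, largest=4)]
        out = group_by_cluster_size(one, total_dmg_count=1)
        assert out["percentages"] == {"ge2": 100.0, "ge3": 100.0, "gt3": 100.0}
        with pytest.raises(DataError):
            group_by_cluster_size([], total_dmg_count=0)

    def test_nesting_invariant_on_pipeline_output(self, small_result):
        grouping = small_result.gene_grouping
        if grouping is None:
            pytest.skip("no DMGs in fixture")
        c = grouping["counts"]
        assert c["ge2"] >= c["ge3"] >= c["gt3"]


class TestGenesetEnrichment:
    def test_hypergeometric_tail_matches_exact_summation(self):
        universe = [f"g{i}" for i in range(100)]
        gene_set = {"S": set(universe[:10])}
        gene_list = universe[:5] + universe[50:55]  # 5 of 10 hits
        df = geneset_enrichment(gene_list, gene_set, universe)
        N, K, n = 100, 10, 10
        expected = sum(
            math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)
            for k in range(5, min(K, n) + 1))
        assert df.p_value[0] == pytest.approx(expected, rel=1e-10)

    def test_list_equal_to_universe_gives_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        df = geneset_enrichment(universe, {"S": set(universe[:7])}, universe)
        assert df.p_value[0] == pytest.approx(1.0)

    def test_empty_list_is_error(self):
        with pytest.raises(DataError):
            geneset_enrichment([], {"S": {"a"}}, ["a"])

    def test_disjoint_set_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            df = geneset_enrichment(["a"], {"S": {"zzz"}}, ["a", "b"])
        assert len(df) == 0

    def test_read_gmt(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("morphogenesis\tdesc\tHOXB7\tSOX1\nother\tdesc\tFOXE1\n")
        sets = read_gmt(p)
        assert sets["morphogenesis"] == {"HOXB7", "SOX1"}
        assert sets["other"] == {"FOXE1"}
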