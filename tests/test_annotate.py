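import itertools
import math

import numpy as np
import pytest

from multicistrome.annotate import (
    genomic_context,
    hypergeometric_enrichment,
    link_regions_to_genes,
)
from multicistrome.intervals import Gene, GenomicInterval, IntervalSet


def iset(*coords):
    return IntervalSet(GenomicInterval("chr1", a, b) for a, b in coords)


class TestGenomicContext:
    def test_no_annotation_is_all_distal(self):
        dist = genomic_context(iset((0, 100), (500, 600)), genes=[])
        assert dist["distal_intergenic"] == 100.0

    def test_region_on_tss_is_promoter(self):
        genes = [Gene("g1", "chr1", 5000, "+", 5000, 15000)]
        dist = genomic_context(iset((4950, 5050)), genes, promoter_flank=1000)
        assert dist["promoter"] == 100.0

    def test_gene_body_without_exons_is_intron(self):
        genes = [Gene("g1", "chr1", 5000, "+", 5000, 15000)]
        dist = genomic_context(iset((9000, 9100)), genes, promoter_flank=1000)
        assert dist["intron"] == 100.0

    def test_exon_precedence_over_intron(self):
        genes = [Gene("g1", "chr1", 5000, "+", 5000, 15000)]
        exons = {"g1": iset((8900, 9200))}
        dist = genomic_context(iset((9000, 9100)), genes, 1000, exons=exons)
        assert dist["exon"] == 100.0

    def test_downstream_is_strand_aware(self):
        plus = [Gene("g1", "chr1", 5000, "+", 5000, 15000)]
        minus = [Gene("g1", "chr1", 14999, "-", 5000, 15000)]
        region = iset((15200, 15400))  # past the + gene end
        assert genomic_context(region, plus, 1000)["downstream"] == 100.0
        assert genomic_context(region, minus, 1000)["downstream"] == 0.0

    def test_percentages_sum_to_100(self):
        genes = [Gene("g1", "chr1", 5000, "+", 5000, 15000)]
        dist = genomic_context(iset((4950, 5050), (9000, 9100), (50_000, 50_100)), genes)
        assert sum(dist.values()) == pytest.approx(100.0, abs=0.01)

    def test_empty_region_set_rejected(self):
        with pytest.raises(ValueError):
            genomic_context(IntervalSet(), genes=[])


class TestLinkRegionsToGenes:
    GENES = [
        Gene("near", "chr1", 110_000, "+"),
        Gene("far", "chr1", 130_000, "+"),
    ]

    def test_nearest_gene_within_window_wins(self):
        linked, table = link_regions_to_genes(
            iset((99_500, 100_500)), self.GENES, window=20_000
        )
        assert linked == {"near"}
        assert table.distance.tolist() == [10_000]

    def test_beyond_window_unassigned(self):
        genes = [Gene("g", "chr1", 125_000, "+")]
        linked, table = link_regions_to_genes(iset((99_500, 100_500)), genes, 20_000)
        assert linked == set()
        assert table.empty

    def test_equidistant_ties_keep_all_genes(self):
        genes = [
            Gene("left", "chr1", 95_000, "+"),
            Gene("right", "chr1", 105_000, "+"),
        ]
        linked, table = link_regions_to_genes(iset((99_500, 100_500)), genes, 20_000)
        assert linked == {"left", "right"}
        assert len(table) == 2

    def test_huge_window_links_every_region_with_a_chrom_gene(self):
        rng = np.random.default_rng(0)
        regions = IntervalSet(
            GenomicInterval("chr1", int(s), int(s) + 100)
            for s in rng.integers(0, 10**6, 30)
        )
        genes = [Gene("g", "chr1", 500_000, "+")]
        linked, table = link_regions_to_genes(regions, genes, window=10**9)
        assert len(table) == 30 and linked == {"g"}

    def test_window_must_be_positive(self):
        with pytest.raises(ValueError):
            link_regions_to_genes(iset((0, 10)), self.GENES, window=0)


def brute_force_hypergeom_p(universe, gene_set, query):
    """Exhaustive upper-tail p over all C(N, n) draws of |query| genes."""
    k_obs = len(query & gene_set)
    hits = total = 0
    for draw in itertools.combinations(sorted(universe), len(query)):
        total += 1
        hits += len(set(draw) & gene_set) >= k_obs
    return hits / total


class TestHypergeometricEnrichment:
    def test_closed_form_example(self):
        universe = {f"g{i}" for i in range(10)}
        gene_set = {f"g{i}" for i in range(5)}
        query = {"g0", "g1", "g2", "g3"}
        res = hypergeometric_enrichment(query, {"s": gene_set}, universe)
        assert res[0].p_value == pytest.approx(5 / 210, rel=1e-12)

    def test_zero_overlap_p_at_most_one(self):
        universe = {f"g{i}" for i in range(10)}
        res = hypergeometric_enrichment(
            {"g9"}, {"s": {f"g{i}" for i in range(5)}}, universe
        )
        assert 0 <= res[0].p_value <= 1

    def test_query_equal_to_set_minimizes_p_among_equal_sizes(self):
        universe = {f"g{i}" for i in range(12)}
        sets = {
            "own": {"g0", "g1", "g2"},
            "other": {"g3", "g4", "g5"},
            "mixed": {"g0", "g6", "g7"},
        }
        res = hypergeometric_enrichment({"g0", "g1", "g2"}, sets, universe)
        assert res[0].set_name == "own"

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_enumeration_small_universe(self, seed):
        rng = np.random.default_rng(seed)
        n_universe = int(rng.integers(6, 13))
        universe = {f"g{i}" for i in range(n_universe)}
        gene_set = set(rng.choice(sorted(universe), size=4, replace=False))
        query = set(rng.choice(sorted(universe), size=5, replace=False))
        res = hypergeometric_enrichment(query, {"s": gene_set}, universe)
        expected = brute_force_hypergeom_p(universe, gene_set, query)
        assert res[0].p_value == pytest.approx(expected, abs=1e-12)

    def test_bh_is_monotone_in_rank_order(self):
        rng = np.random.default_rng(1)
        universe = {f"g{i}" for i in range(50)}
        sets = {
            f"s{j}": set(rng.choice(sorted(universe), size=10, replace=False))
            for j in range(8)
        }
        query = set(rng.choice(sorted(universe), size=12, replace=False))
        res = hypergeometric_enrichment(query, sets, universe, top_n=8)
        by_p = sorted(res, key=lambda r: r.p_value)
        fdrs = [r.fdr for r in by_p]
        assert fdrs == sorted(fdrs)
        assert all(r.fdr >= r.p_value - 1e-12 for r in res)

    def test_genes_outside_universe_dropped(self):
        universe = {"a", "b", "c", "d"}
        res = hypergeometric_enrichment(
            {"a", "zzz"}, {"s": {"a", "b", "yyy"}}, universe
        )
        assert res[0].query_size == 1
        assert res[0].set_size == 2

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment({"a"}, {"s": {"a"}}, set())
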