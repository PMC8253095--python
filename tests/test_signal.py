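import itertools

import numpy as np
import pytest
from scipy import stats

from conftest import brute_force_overlap, random_interval_set
from multicistrome.intervals import Genome, GenomicInterval, IntervalSet
from multicistrome.signal import (
    FragmentSet,
    build_count_matrix,
    count_fragments_in_regions,
    cpm_normalize,
    log_counts,
    rank_sum_test,
    signal_matrix,
)


def frags(*coords, sample="s", factor="AR", library_size=0):
    return FragmentSet(
        sample_id=sample,
        factor=factor,
        fragments=IntervalSet(GenomicInterval("chr1", a, b) for a, b in coords),
        library_size=library_size,
    )


class TestCounting:
    def test_any_overlap_counts_both_fragments(self):
        f = frags((0, 65), (100, 165))
        regions = IntervalSet([GenomicInterval("chr1", 50, 150)])
        assert count_fragments_in_regions(f, regions).tolist() == [2]

    def test_no_fragments_gives_zeros(self):
        f = frags()
        regions = IntervalSet([GenomicInterval("chr1", 0, 100)])
        assert count_fragments_in_regions(f, regions).tolist() == [0]

    def test_abutting_fragment_not_counted(self):
        f = frags((100, 165))
        regions = IntervalSet([GenomicInterval("chr1", 50, 100)])
        assert count_fragments_in_regions(f, regions).tolist() == [0]

    def test_fragment_spanning_two_regions_increments_both(self):
        f = frags((90, 160))
        regions = IntervalSet(
            [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 150, 200)]
        )
        assert count_fragments_in_regions(f, regions).tolist() == [1, 1]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        f = FragmentSet("s", "AR", random_interval_set(rng, 150))
        regions = random_interval_set(rng, 40)
        expected = np.zeros(len(regions), dtype=int)
        for i, _ in brute_force_overlap(regions, f.fragments):
            expected[i] += 1
        assert count_fragments_in_regions(f, regions).tolist() == expected.tolist()

    def test_disjoint_region_counts_bounded_by_library(self):
        rng = np.random.default_rng(9)
        f = FragmentSet("s", "AR", random_interval_set(rng, 200, max_len=10))
        from multicistrome.intervals import merge_intervals

        regions = merge_intervals(random_interval_set(rng, 50))
        # a fragment can span two merged regions only via the gap, but each
        # disjoint region counts it once; totals stay within a small factor
        counts = count_fragments_in_regions(f, regions)
        assert counts.sum() <= 2 * f.library_size


class TestCPM:
    def test_unit_library(self):
        f = frags(*([(0, 10)] * 5), library_size=10**6)
        cm = build_count_matrix([f], IntervalSet([GenomicInterval("chr1", 0, 20)]))
        cpm_normalize(cm)
        assert cm.cpm[0, 0] == pytest.approx(5.0)

    def test_two_million_library_halves(self):
        f = frags(*([(0, 10)] * 4), library_size=2 * 10**6)
        cm = build_count_matrix([f], IntervalSet([GenomicInterval("chr1", 0, 20)]))
        cpm_normalize(cm)
        assert cm.cpm[0, 0] == pytest.approx(2.0)

    def test_zero_library_rejected(self):
        f = frags((0, 10))
        cm = build_count_matrix([f], IntervalSet([GenomicInterval("chr1", 0, 20)]))
        cm.library_sizes = np.array([0])
        with pytest.raises(ValueError):
            cpm_normalize(cm)

    def test_all_zero_column_stays_zero(self):
        f = frags((0, 10), library_size=100)
        cm = build_count_matrix([f], IntervalSet([GenomicInterval("chr1", 500, 600)]))
        cpm_normalize(cm)
        assert cm.cpm[0, 0] == 0.0


class TestSignalMatrix:
    GENOME = Genome(chrom_sizes={"chr1": 20_000})

    def test_bin_count_is_two_flank_over_bin_size(self):
        f = frags((0, 65))
        m = signal_matrix(
            f, IntervalSet([GenomicInterval("chr1", 9000, 9400)]), self.GENOME,
            flank=2000, bin_size=25,
        )
        assert m.values.shape == (1, 160)
        assert m.n_bins == 160

    def test_flat_track_gives_equal_bins(self):
        tiles = [(i * 65, (i + 1) * 65) for i in range(20_000 // 65)]
        f = frags(*tiles)
        m = signal_matrix(
            f, IntervalSet([GenomicInterval("chr1", 9000, 9400)]), self.GENOME,
            flank=2000, bin_size=25,
        )
        assert np.allclose(m.values, m.values[0, 0])

    def test_out_of_bounds_bins_are_missing(self):
        f = frags((0, 65))
        m = signal_matrix(
            f, IntervalSet([GenomicInterval("chr1", 100, 200)]), self.GENOME,
            flank=2000, bin_size=25,
        )
        assert np.isnan(m.values[0, 0])  # window starts before the chromosome
        assert not np.isnan(m.values[0, -1])

    def test_flank_must_divide_by_bin_size(self):
        with pytest.raises(ValueError):
            signal_matrix(
                frags((0, 65)), IntervalSet([GenomicInterval("chr1", 500, 600)]),
                self.GENOME, flank=2000, bin_size=30,
            )

    def test_display_order_descends_by_row_sum(self):
        f = frags(*([(9000, 9065)] * 5), (15000, 15065))
        regions = IntervalSet(
            [GenomicInterval("chr1", 14900, 15100), GenomicInterval("chr1", 8900, 9100)]
        )
        m = signal_matrix(f, regions, self.GENOME, flank=500, bin_size=25)
        assert m.display_order().tolist() == [1, 0]


class TestRankSum:
    def test_separated_triples_exact_p(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)

    def test_identical_samples_degenerate(self):
        res = rank_sum_test([2, 2, 2], [2, 2, 2])
        assert res.p_value == 1.0
        assert res.degenerate

    def test_equal_samples_p_one(self):
        res = rank_sum_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p_value == pytest.approx(1.0)

    def test_exact_matches_full_enumeration_with_ties(self):
        rng = np.random.default_rng(4)
        a = rng.integers(0, 4, size=5).astype(float)
        b = rng.integers(0, 4, size=6).astype(float)
        res = rank_sum_test(a, b)
        assert res.method == "exact"
        # independent enumeration over all assignments
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        n_a = len(a)
        mean_u = n_a * len(b) / 2
        u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
        hits = total = 0
        for idx in itertools.combinations(range(len(pooled)), n_a):
            u = ranks[list(idx)].sum() - n_a * (n_a + 1) / 2
            total += 1
            hits += abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12
        assert res.p_value == pytest.approx(hits / total, abs=1e-9)

    def test_large_separated_normals_are_significant(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 200)
        b = rng.normal(1, 1, 200)
        res = rank_sum_test(a, b)
        assert res.method == "normal-approximation"
        assert res.p_value < 0.005

    @pytest.mark.parametrize("seed", range(5))
    def test_normal_approximation_close_to_exact_midsize(self, seed):
        # compare asymptotic p against exact enumeration for 8 <= n <= 20 total
        rng = np.random.default_rng(seed)
        n_a, n_b = 4, int(rng.integers(8, 17))  # keep n_a*n_b <= 64
        a = rng.normal(0, 1, n_a)
        b = rng.normal(0.5, 1, n_b)
        exact = rank_sum_test(a, b)
        assert exact.method == "exact"
        approx = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert abs(exact.p_value - approx.pvalue) < 0.02

    def test_log_counts_is_natural_log_plus_one(self):
        assert log_counts([0, np.e - 1]).tolist() == pytest.approx([0.0, 1.0])
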