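import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import brute_force_overlap, random_interval_set
from multicistrome.intervals import (
    BedParseError,
    Genome,
    GenomicInterval,
    IntervalSet,
    merge_intervals,
    overlap_query,
    read_bed,
    read_chrom_sizes,
    read_genes_bed,
    read_genes_gtf,
    read_gmt,
    write_bed,
)


class TestGenomicInterval:
    def test_rejects_inverted_and_negative_coordinates(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)

    def test_half_open_abutment_does_not_overlap(self):
        a = GenomicInterval("chr1", 0, 10)
        assert not a.overlaps(GenomicInterval("chr1", 10, 20))
        assert a.overlaps(GenomicInterval("chr1", 9, 20))
        assert not a.overlaps(GenomicInterval("chr2", 0, 10))


class TestReadBed:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\n")
        s = read_bed(p)
        assert len(s) == 1
        assert s[0] == GenomicInterval("chr1", 0, 100)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert len(read_bed(p)) == 0

    def test_out_of_order_records_keep_order_and_clear_sorted_flag(self, tmp_path):
        p = tmp_path / "u.bed"
        p.write_text("chr1\t500\t600\nchr1\t0\t100\nchr1\t200\t300\n")
        s = read_bed(p)
        assert len(s) == 3
        assert not s.sorted
        assert s[0].start == 500  # order preserved

    @pytest.mark.parametrize(
        "line", ["chr1\tx\t100", "chr1\t100\t50", "chr1\t5"], ids=["nonint", "inverted", "short"]
    )
    def test_malformed_line_names_line_number(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t10\n" + line + "\n")
        with pytest.raises(BedParseError, match=":2"):
            read_bed(p)

    def test_comment_and_track_lines_skipped(self, tmp_path):
        p = tmp_path / "c.bed"
        p.write_text("# comment\ntrack name=x\nbrowser pos\nchr1\t0\t10\n")
        assert len(read_bed(p)) == 1

    def test_round_trip_is_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        s = random_interval_set(rng, 50)
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        write_bed(s, p1)
        write_bed(read_bed(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert read_bed(p1) == s


class TestMerge:
    def test_overlapping_pair_unions(self):
        s = IntervalSet([GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 50, 150)])
        assert merge_intervals(s).intervals == [GenomicInterval("chr1", 0, 150)]

    def test_disjoint_set_unchanged(self):
        s = IntervalSet([GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300)])
        assert merge_intervals(s).intervals == s.intervals

    def test_gap_bridges_separation(self):
        s = IntervalSet([GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 110, 200)])
        assert merge_intervals(s, gap=10).intervals == [GenomicInterval("chr1", 0, 200)]
        assert len(merge_intervals(s, gap=9)) == 2

    def test_total_bp_conserved_at_gap_zero_for_disjoint(self):
        rng = np.random.default_rng(1)
        s = random_interval_set(rng, 60)
        merged = merge_intervals(s)
        assert merged.merged and merged.sorted
        # covered bp of the merged set equals the union size computed per-bp
        covered = set()
        for iv in s:
            covered.update((iv.chrom, p) for p in range(iv.start, iv.end))
        assert merged.total_bp() == len(covered)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1), st.integers(0, 20))
    def test_merge_idempotent(self, seed, gap):
        s = random_interval_set(np.random.default_rng(seed), 40)
        once = merge_intervals(s, gap=gap)
        twice = merge_intervals(once, gap=gap)
        assert once.intervals == twice.intervals


class TestOverlapQuery:
    def test_partial_overlap_pair(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 10)])
        b = IntervalSet([GenomicInterval("chr1", 5, 15)])
        assert overlap_query(a, b) == [(0, 0)]
        assert overlap_query(a, b, min_bp=5) == [(0, 0)]
        assert overlap_query(a, b, min_bp=6) == []

    def test_abutment_is_not_overlap(self):
        a = IntervalSet([GenomicInterval("chr1", 0, 10)])
        b = IntervalSet([GenomicInterval("chr1", 10, 20)])
        assert overlap_query(a, b) == []

    def test_self_query_of_disjoint_set_is_diagonal(self):
        s = IntervalSet(
            [
                GenomicInterval("chr1", 0, 10),
                GenomicInterval("chr1", 20, 30),
                GenomicInterval("chr2", 0, 10),
            ]
        )
        assert overlap_query(s, s) == [(0, 0), (1, 1), (2, 2)]

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("min_bp", [1, 3])
    def test_matches_brute_force_on_random_sets(self, seed, min_bp):
        rng = np.random.default_rng(seed)
        a = random_interval_set(rng, int(rng.integers(0, 100)))
        b = random_interval_set(rng, int(rng.integers(0, 100)))
        assert sorted(overlap_query(a, b, min_bp)) == sorted(
            brute_force_overlap(a, b, min_bp)
        )
        # symmetric in content with arguments swapped
        assert sorted((j, i) for i, j in overlap_query(a, b, min_bp)) == sorted(
            overlap_query(b, a, min_bp)
        )


class TestGenomeAndReaders:
    def test_genome_validates_sequence_length(self):
        with pytest.raises(ValueError):
            Genome(chrom_sizes={"chr1": 10}, sequence={"chr1": "ACGT"})
        with pytest.raises(ValueError):
            Genome(chrom_sizes={"chr1": 0})

    def test_chromosome_names_matched_exactly(self):
        g = Genome(chrom_sizes={"chr1": 100})
        s = IntervalSet([GenomicInterval("1", 0, 10), GenomicInterval("chr1", 0, 10)])
        assert s.validate_against(g) == ["1"]

    def test_chrom_sizes_reader(self, tmp_path):
        p = tmp_path / "g.sizes"
        p.write_text("chr1\t1000\nchr2\t500\n")
        assert read_chrom_sizes(p) == {"chr1": 1000, "chr2": 500}

    def test_genes_bed_strand_aware_tss(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t100\t200\tgplus\t0\t+\nchr1\t300\t400\tgminus\t0\t-\n")
        genes = read_genes_bed(p)
        assert genes[0].tss == 100
        assert genes[1].tss == 399

    def test_genes_gtf_one_based_conversion(self, tmp_path):
        p = tmp_path / "genes.gtf"
        p.write_text(
            'chr1\tsrc\tgene\t101\t200\t.\t+\t.\tgene_id "g1";\n'
            'chr1\tsrc\texon\t101\t150\t.\t+\t.\tgene_id "g1";\n'
            'chr1\tsrc\tgene\t301\t400\t.\t-\t.\tgene_id "g2";\n'
        )
        genes = read_genes_gtf(p)
        assert [g.gene_id for g in genes] == ["g1", "g2"]
        assert genes[0].tss == 100  # GTF start 101 -> 0-based 100
        assert genes[1].tss == 399

    def test_duplicate_gene_ids_rejected(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t0\t10\tg\t0\t+\nchr1\t20\t30\tg\t0\t+\n")
        with pytest.raises(BedParseError, match="duplicate"):
            read_genes_bed(p)

    def test_gmt_reader(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("SET_A\tdesc\tg1\tg2\nSET_B\tdesc\tg3\n")
        sets = read_gmt(p)
        assert sets == {"SET_A": {"g1", "g2"}, "SET_B": {"g3"}}
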