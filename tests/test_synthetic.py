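import hashlib
from pathlib import Path

import numpy as np
import pytest

from conftest import brute_force_overlap
from multicistrome.consensus import PeakSet, build_membership
from multicistrome.intervals import (
    IntervalSet,
    merge_intervals,
    read_bed,
    read_genes_bed,
    read_genome,
    read_gmt,
)
from multicistrome.motifs import read_jaspar, scan_pwm
from multicistrome.synthetic import (
    FACTORS,
    PEAK_FACTORS,
    SimulationConfig,
    SyntheticTruth,
    interval_jaccard,
    simulate_dataset,
    truth_compare,
)


def tree_digest(root: Path) -> dict[str, str]:
    return {
        str(p.relative_to(root)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }


def test_same_seed_gives_byte_identical_outputs(small_config, tmp_path):
    d1 = simulate_dataset(small_config, tmp_path / "a")
    d2 = simulate_dataset(small_config, tmp_path / "b")
    assert tree_digest(d1.root) == tree_digest(d2.root)


def test_different_seeds_differ(small_config, small_dataset, tmp_path):
    import dataclasses

    other = dataclasses.replace(small_config, seed=small_config.seed + 1)
    d2 = simulate_dataset(other, tmp_path / "c")
    assert tree_digest(small_dataset.root) != tree_digest(d2.root)


def test_caller1_peak_count_is_core_plus_specific(small_dataset):
    cfg = small_dataset.config
    for s in cfg.sample_ids:
        peaks = read_bed(small_dataset.caller_bed(s, "AR", 1))
        assert len(peaks) == cfg.n_core_peaks + cfg.n_specific_per_sample
        assert peaks.sorted and peaks.merged


def test_caller2_is_jittered_with_dropout(small_dataset):
    cfg = small_dataset.config
    c1 = read_bed(small_dataset.caller_bed("S1", "AR", 1))
    c2 = read_bed(small_dataset.caller_bed("S1", "AR", 2))
    assert len(c2) <= len(c1)
    # every surviving caller-2 peak overlaps its caller-1 source
    assert {j for _, j in brute_force_overlap(c2, c1)} is not None
    hit = {i for i, _ in brute_force_overlap(c2, c1)}
    assert hit == set(range(len(c2)))


def test_all_outputs_reparse_through_io_layer(small_dataset):
    genome = read_genome(small_dataset.chrom_sizes, small_dataset.fasta)
    assert set(genome.sequence) == set(genome.chrom_sizes)
    genes = read_genes_bed(small_dataset.genes_bed)
    assert len(genes) == small_dataset.config.n_genes
    sets = read_gmt(small_dataset.gene_sets_gmt)
    assert "ESSENTIAL_GENES" in sets
    pwms = read_jaspar(small_dataset.pwm_library)
    assert len(pwms) == small_dataset.config.n_library_pwms
    for s in small_dataset.config.sample_ids:
        for f in FACTORS:
            frags = read_bed(small_dataset.fragments_bed(s, f))
            assert len(frags) > 0
            for iv in frags:
                assert iv.end <= genome.chrom_sizes[iv.chrom]
        for f in PEAK_FACTORS:
            read_bed(small_dataset.caller_bed(s, f, 1))
            read_bed(small_dataset.caller_bed(s, f, 2))


def test_truth_round_trips_through_json(small_dataset):
    loaded = SyntheticTruth.from_json(small_dataset.truth_json)
    assert loaded == small_dataset.truth


def test_truth_invariants_hold_by_construction(small_dataset):
    truth = small_dataset.truth
    cfg = small_dataset.config
    core = truth.core_set()
    sets = [core] + [truth.specific_set(s) for s in cfg.sample_ids]
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            assert brute_force_overlap(sets[i], sets[j]) == []
    for s in cfg.sample_ids:
        assert set(truth.active_specific[s]) <= set(truth.specific_regions[s])
    gene_ids = {g.gene_id for g in read_genes_bed(small_dataset.genes_bed)}
    assert set(truth.de_genes) <= gene_ids
    assert truth.shared_fraction == pytest.approx(
        cfg.n_core_peaks / (cfg.n_core_peaks + cfg.n_specific_per_sample)
    )


def test_planted_motif_occurrences_found_in_genome(small_dataset):
    genome = read_genome(small_dataset.chrom_sizes, small_dataset.fasta)
    pwm = read_jaspar(small_dataset.pwm_library)[0]
    assert pwm.motif_id == small_dataset.truth.motif_id
    for chrom, offset in small_dataset.truth.motif_placements[:10]:
        window = genome.sequence[chrom][offset - 5 : offset + len(pwm) + 5]
        hits = scan_pwm(window, pwm, score_fraction=0.9)
        assert any(pos == 5 for pos, _ in hits)


def test_fragment_totals_match_configured_expectation(default_dataset):
    cfg = default_dataset.config
    for key, expected in default_dataset.truth.expected_fragments.items():
        s, f = key.split("_", 1)
        observed = len(read_bed(default_dataset.fragments_bed(s, f)))
        tol = 0.01 if f != "H3K27me3" else 0.035  # pure-Poisson track: ~3 sigma
        assert abs(observed / expected - 1) < tol, key


def test_truth_compare_on_truth_itself_is_perfect(small_dataset):
    truth = small_dataset.truth
    cfg = small_dataset.config
    peak_sets = [
        PeakSet(
            s,
            "AR",
            merge_intervals(
                IntervalSet(
                    list(truth.core_set()) + list(truth.specific_set(s))
                )
            ),
        )
        for s in cfg.sample_ids
    ]
    table = build_membership(peak_sets)
    report = truth_compare(
        truth,
        table,
        selected_active={s: truth.active_set(s) for s in cfg.sample_ids},
        motif_ranking=[truth.motif_id, "DECOY"],
        de_passed=sorted(truth.de_genes),
    )
    assert report["shared_fraction_recovered"] == pytest.approx(
        truth.shared_fraction
    )
    assert report["jaccard_core"] == 1.0
    assert all(v == 1.0 for v in report["jaccard_specific"].values())
    assert all(v == 1.0 for v in report["jaccard_active"].values())
    assert report["planted_motif_rank"] == 1
    assert report["de_precision"] == report["de_recall"] == 1.0


def test_truth_compare_rejects_mismatched_samples(small_dataset):
    truth = small_dataset.truth
    table = build_membership(
        [
            PeakSet("X", "AR", truth.core_set()),
            PeakSet("Y", "AR", truth.specific_set("S1")),
        ]
    )
    with pytest.raises(ValueError, match="sample ids"):
        truth_compare(truth, table)


def test_infeasible_genome_rejected_before_writing(tmp_path):
    cfg = SimulationConfig(
        seed=0, n_chroms=1, chrom_length=50_000, n_core_peaks=200
    )
    with pytest.raises(ValueError, match="too small"):
        simulate_dataset(cfg, tmp_path / "x")


def test_interval_jaccard_overlap_semantics():
    from multicistrome.intervals import GenomicInterval

    a = IntervalSet([GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300)])
    b = IntervalSet([GenomicInterval("chr1", 50, 150)])
    assert interval_jaccard(a, b) == pytest.approx(1 / 2)
    assert interval_jaccard(a, a) == 1.0
    assert interval_jaccard(IntervalSet(), IntervalSet()) == 1.0
    assert interval_jaccard(a, IntervalSet()) == 0.0
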