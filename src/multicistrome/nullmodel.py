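"""Matched-shuffle null: random regions matching a source set in number and
length, placed anywhere in the genome but rejected if they touch an exclusion
set (by default the source itself).

This is the "factor-specific noise" construction: for each factor, all called
peaks are concatenated and length-matched random coordinates not found in the
concatenation are drawn. Placed intervals may overlap one another — the null
matches the length multiset, not the disjointness, of the source.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import Genome, GenomicInterval, IntervalSet


class ShufflePlacementError(RuntimeError):
    """An interval could not be placed within the attempt budget."""


@dataclass
class NoiseRegionSet:
    intervals: IntervalSet
    source_factor: str
    seed: int
    attempts_used: int


def _exclusion_index(exclusion: IntervalSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome merged (starts, ends) arrays for O(log n) overlap checks."""
    from .intervals import merge_intervals

    merged = merge_intervals(exclusion, gap=0)
    idx: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, rows in merged.by_chrom().items():
        idx[chrom] = (rows[:, 0].copy(), rows[:, 1].copy())
    return idx


def _overlaps_exclusion(
    idx: dict[str, tuple[np.ndarray, np.ndarray]], chrom: str, start: int, end: int
) -> bool:
    entry = idx.get(chrom)
    if entry is None:
        return False
    starts, ends = entry
    i = int(np.searchsorted(starts, end, side="left"))  # first start >= end
    return i > 0 and ends[i - 1] > start


def matched_shuffle(
    source: IntervalSet,
    genome: Genome,
    exclusion: IntervalSet | None = None,
    seed: int = 0,
    max_attempts_per_interval: int = 1000,
    source_factor: str = "",
    preserve_chromosome: bool = False,
) -> NoiseRegionSet:
    """Draw one random placement per source interval, avoiding the exclusion.

    Each placement picks a chromosome with probability proportional to its
    length (or keeps the source chromosome when ``preserve_chromosome``), then
    a uniform start such that the interval fits; it is accepted iff it shares
    zero bases with the exclusion set. Deterministic for a fixed seed.

    ``exclusion`` defaults to the source set itself (the concatenated peaks).
    """
    if exclusion is None:
        exclusion = source
    rng = np.random.default_rng(seed)
    excl_idx = _exclusion_index(exclusion)
    chroms = list(genome.chrom_sizes)
    sizes = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    probs = sizes / sizes.sum()

    placed: list[GenomicInterval] = []
    attempts_total = 0
    for iv in source:
        length = iv.length
        placed_ok = False
        for _ in range(max_attempts_per_interval):
            attempts_total += 1
            if preserve_chromosome:
                chrom = iv.chrom
                csize = genome.chrom_sizes[chrom]
            else:
                ci = int(rng.choice(len(chroms), p=probs))
                chrom, csize = chroms[ci], int(sizes[ci])
            if length > csize:
                continue
            start = int(rng.integers(0, csize - length + 1))
            end = start + length
            if not _overlaps_exclusion(excl_idx, chrom, start, end):
                placed.append(GenomicInterval(chrom, start, end, name=iv.name))
                placed_ok = True
                break
        if not placed_ok:
            raise ShufflePlacementError(
                f"could not place interval {iv.chrom}:{iv.start}-{iv.end} "
                f"(length {length}) within {max_attempts_per_interval} attempts"
            )
    return NoiseRegionSet(
        intervals=IntervalSet(placed),
        source_factor=source_factor,
        seed=seed,
        attempts_used=attempts_total,
    )
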