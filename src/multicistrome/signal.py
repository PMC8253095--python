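"""Fragment counting in regions, CPM normalization, binned signal matrices
centered on region midpoints, and rank-sum comparisons between region classes.

Fragments are counted by any-overlap (>=1 bp, half-open), so a fragment
spanning two regions increments both. CPM = count * 1e6 / library_size.
Signal matrices hold mean per-bp CPM coverage in fixed-width bins across
``2*flank`` bp centered on each region midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import Genome, IntervalSet, read_bed


@dataclass
class FragmentSet:
    """Aligned sequenced fragments of one sample/factor.

    ``library_size`` defaults to the number of fragments present but may be
    larger when clipped/filtered records were dropped upstream.
    """

    sample_id: str
    factor: str
    fragments: IntervalSet
    library_size: int = 0

    def __post_init__(self) -> None:
        if self.library_size == 0:
            self.library_size = len(self.fragments)
        if self.library_size < len(self.fragments):
            raise ValueError("library_size smaller than fragment count")
        # per-chromosome sorted starts/ends for O(log n) counting
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, rows in self.fragments.by_chrom().items():
            self._starts[chrom] = np.sort(rows[:, 0])
            self._ends[chrom] = np.sort(rows[:, 1])

    @classmethod
    def from_bed(cls, path: str | Path, sample_id: str, factor: str) -> "FragmentSet":
        return cls(sample_id=sample_id, factor=factor, fragments=read_bed(path))

    @classmethod
    def from_bam(
        cls, path: str | Path, sample_id: str, factor: str, min_mapq: int = 20
    ) -> "FragmentSet":
        """Mapped primary alignments with MAPQ > min_mapq, as aligned-length
        fragments (no extension)."""
        import pysam

        from .intervals import GenomicInterval

        ivs = []
        with pysam.AlignmentFile(str(path)) as bam:
            for read in bam.fetch(until_eof=True):
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.mapping_quality <= min_mapq
                ):
                    continue
                ivs.append(
                    GenomicInterval(
                        read.reference_name, read.reference_start, read.reference_end
                    )
                )
        return cls(sample_id=sample_id, factor=factor, fragments=IntervalSet(ivs))

    def count_in(self, regions: IntervalSet) -> np.ndarray:
        """Any-overlap fragment count per region (in region order)."""
        counts = np.zeros(len(regions), dtype=np.int64)
        for i, iv in enumerate(regions):
            starts = self._starts.get(iv.chrom)
            if starts is None:
                continue
            ends = self._ends[iv.chrom]
            n_start_before_end = np.searchsorted(starts, iv.end, side="left")
            n_end_before_start = np.searchsorted(ends, iv.start, side="right")
            counts[i] = int(n_start_before_end - n_end_before_start)
        return counts

    def coverage(self, chrom: str, length: int) -> np.ndarray:
        """Per-bp fragment coverage over one chromosome."""
        cov = np.zeros(length + 1, dtype=np.float64)
        rows = self.fragments.by_chrom().get(chrom)
        if rows is not None:
            starts = np.clip(rows[:, 0], 0, length)
            ends = np.clip(rows[:, 1], 0, length)
            np.add.at(cov, starts, 1.0)
            np.add.at(cov, ends, -1.0)
        return np.cumsum(cov)[:length]


@dataclass
class CountMatrix:
    """Regions x samples fragment counts with an optional CPM view."""

    regions: IntervalSet
    samples: list[str]
    counts: np.ndarray  # regions x samples, int
    library_sizes: np.ndarray  # per sample
    cpm: np.ndarray | None = None

    def to_frame(self, normalized: bool = False) -> pd.DataFrame:
        values = self.cpm if normalized else self.counts
        if values is None:
            raise ValueError("CPM view not computed; call cpm_normalize first")
        index = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in self.regions]
        return pd.DataFrame(values, index=index, columns=self.samples)


@dataclass
class SignalMatrix:
    """Regions x bins mean per-bp CPM coverage, centered on region midpoints.

    Bins falling outside the chromosome are NaN. ``values`` rows follow
    ``regions`` order; display ordering (descending row sum) is applied only
    on export.
    """

    regions: IntervalSet
    flank: int
    bin_size: int
    values: np.ndarray
    sample_id: str = ""
    factor: str = ""

    @property
    def n_bins(self) -> int:
        return 2 * self.flank // self.bin_size

    def profile(self) -> np.ndarray:
        """Column-mean signal profile (NaN-aware)."""
        return np.nanmean(self.values, axis=0)

    def display_order(self) -> np.ndarray:
        """Row indices sorted by descending row sum (heatmap convention)."""
        sums = np.nansum(self.values, axis=1)
        return np.argsort(-sums, kind="stable")

    def to_frame(self) -> pd.DataFrame:
        index = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in self.regions]
        cols = [
            f"{-self.flank + i * self.bin_size}"
            for i in range(self.n_bins)
        ]
        return pd.DataFrame(self.values, index=index, columns=cols)


@dataclass
class RankSumResult:
    statistic: float  # Mann-Whitney U of sample a
    p_value: float
    n_a: int
    n_b: int
    method: str  # "exact" | "normal-approximation"
    degenerate: bool = False


def count_fragments_in_regions(
    frags: FragmentSet, regions: IntervalSet
) -> np.ndarray:
    """Column of a CountMatrix: any-overlap fragment counts per region."""
    return frags.count_in(regions)


def build_count_matrix(
    fragment_sets: list[FragmentSet], regions: IntervalSet
) -> CountMatrix:
    counts = np.column_stack([f.count_in(regions) for f in fragment_sets])
    return CountMatrix(
        regions=regions,
        samples=[f.sample_id for f in fragment_sets],
        counts=counts,
        library_sizes=np.array([f.library_size for f in fragment_sets]),
    )


def cpm_normalize(m: CountMatrix) -> CountMatrix:
    """Attach the counts-per-million view: counts * 1e6 / library_size."""
    if np.any(m.library_sizes <= 0):
        raise ValueError("all library sizes must be positive for CPM")
    m.cpm = m.counts * 1e6 / m.library_sizes[np.newaxis, :]
    return m


def signal_matrix(
    frags: FragmentSet,
    regions: IntervalSet,
    genome: Genome,
    flank: int = 2000,
    bin_size: int = 25,
) -> SignalMatrix:
    """Binned CPM coverage across 2*flank bp centered on region midpoints.

    Each bin holds mean per-bp fragment coverage scaled by 1e6/library_size.
    Windows truncated by a chromosome edge keep their row; out-of-bounds bins
    are NaN.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    n_bins = 2 * flank // bin_size
    scale = 1e6 / frags.library_size
    cov_cache: dict[str, np.ndarray] = {}
    values = np.full((len(regions), n_bins), np.nan)
    for i, iv in enumerate(regions):
        length = genome.chrom_sizes.get(iv.chrom)
        if length is None:
            raise KeyError(f"chromosome {iv.chrom} not in genome")
        if iv.chrom not in cov_cache:
            cov_cache[iv.chrom] = frags.coverage(iv.chrom, length)
        cov = cov_cache[iv.chrom]
        mid = iv.midpoint
        for b in range(n_bins):
            lo = mid - flank + b * bin_size
            hi = lo + bin_size
            if lo < 0 or hi > length:
                continue  # out-of-bounds bin stays NaN
            values[i, b] = cov[lo:hi].mean() * scale
    return SignalMatrix(
        regions=regions,
        flank=flank,
        bin_size=bin_size,
        values=values,
        sample_id=frags.sample_id,
        factor=frags.factor,
    )


EXACT_MAX_PRODUCT = 64


def rank_sum_test(a, b) -> RankSumResult:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test.

    Exact by enumeration of all C(n_a+n_b, n_a) group assignments when
    n_a*n_b <= 64 (handles ties via midranks); otherwise the normal
    approximation with tie and continuity corrections. When every value in
    both samples is identical the test is degenerate and p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a < 1 or n_b < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        method = "exact" if n_a * n_b <= EXACT_MAX_PRODUCT else "normal-approximation"
        u = n_a * n_b / 2
        return RankSumResult(u, 1.0, n_a, n_b, method, degenerate=True)
    if n_a * n_b <= EXACT_MAX_PRODUCT:
        ranks = stats.rankdata(pooled)  # midranks
        u_obs = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2)
        mean_u = n_a * n_b / 2
        dev_obs = abs(u_obs - mean_u)
        n = n_a + n_b
        hits = total = 0
        for idx in combinations(range(n), n_a):
            u = float(ranks[list(idx)].sum() - n_a * (n_a + 1) / 2)
            total += 1
            if abs(u - mean_u) >= dev_obs - 1e-12:
                hits += 1
        return RankSumResult(u_obs, hits / total, n_a, n_b, "exact")
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return RankSumResult(
        float(res.statistic), float(res.pvalue), n_a, n_b, "normal-approximation"
    )


def log_counts(counts: np.ndarray) -> np.ndarray:
    """Natural log of (count + 1), the transform used for count comparisons."""
    return np.log(np.asarray(counts, dtype=float) + 1.0)
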