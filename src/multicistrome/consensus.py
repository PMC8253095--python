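"""Dual-caller peak intersection, peak-count QC, and cross-sample membership.

A sample's working peak set is the intersection of its two callers' calls
(caller-1 coordinates retained). Across samples, consensus regions are the
merged union of all working peak sets; each region carries a boolean occupancy
vector over samples and a class label:

* ``shared_all`` — occupied by every sample (the UpSet center),
* ``sample_specific`` — occupied by exactly one sample,
* ``partial`` — occupied by more than one but not all samples.

QC excludes a sample/factor whose peak count falls below Q1 - 1.5*IQR of its
factor's counts (linear-interpolation quantiles) or below a hard floor
(default 10 000 peaks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import IntervalSet, merge_intervals, overlapping_indices

SHARED_ALL = "shared_all"
SAMPLE_SPECIFIC = "sample_specific"
PARTIAL = "partial"

DEFAULT_MIN_PEAKS = 10_000


@dataclass
class PeakSet:
    """Consensus peaks of one sample for one factor."""

    sample_id: str
    factor: str
    intervals: IntervalSet
    caller_provenance: tuple[str, str] = ("caller1", "caller2")


@dataclass
class QCRecord:
    sample_id: str
    factor: str
    peak_count: int
    excluded: bool
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.excluded and not self.exclusion_reason:
            raise ValueError("excluded samples must carry an exclusion_reason")


@dataclass
class QCReport:
    records: list[QCRecord]
    fence: float | None  # Q1 - 1.5*IQR, None when quantile rule skipped
    warning: str | None = None

    def excluded_ids(self) -> set[str]:
        return {r.sample_id for r in self.records if r.excluded}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": r.sample_id,
                    "factor": r.factor,
                    "peak_count": r.peak_count,
                    "excluded": r.excluded,
                    "exclusion_reason": r.exclusion_reason,
                }
                for r in self.records
            ]
        )


@dataclass
class MembershipTable:
    """Merged consensus regions with per-sample boolean occupancy."""

    regions: IntervalSet
    samples: list[str]
    occupancy: np.ndarray  # regions x samples, bool
    classes: list[str] = field(default_factory=list)
    specific_sample: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=bool)
        if occ.shape != (len(self.regions), len(self.samples)):
            raise ValueError("occupancy shape mismatch")
        if len(self.regions) and not occ.any(axis=1).all():
            raise ValueError("every consensus region must be occupied by >=1 sample")
        self.occupancy = occ
        if not self.classes:
            self.classes = []
            self.specific_sample = []
            n = occ.sum(axis=1)
            for i in range(occ.shape[0]):
                # a single-sample table degenerates to all sample_specific
                if n[i] == len(self.samples) and len(self.samples) > 1:
                    self.classes.append(SHARED_ALL)
                    self.specific_sample.append(None)
                elif n[i] == 1:
                    self.classes.append(SAMPLE_SPECIFIC)
                    self.specific_sample.append(self.samples[int(occ[i].argmax())])
                else:
                    self.classes.append(PARTIAL)
                    self.specific_sample.append(None)

    def class_counts(self) -> dict[str, int]:
        counts = {SHARED_ALL: 0, SAMPLE_SPECIFIC: 0, PARTIAL: 0}
        for c in self.classes:
            counts[c] += 1
        return counts

    def upset_counts(self) -> dict[tuple[str, ...], int]:
        """Region counts per occupancy pattern (the UpSet bars)."""
        out: dict[tuple[str, ...], int] = {}
        for row in self.occupancy:
            key = tuple(s for s, present in zip(self.samples, row) if present)
            out[key] = out.get(key, 0) + 1
        return out

    def subset(self, cls: str, sample_id: str | None = None) -> IntervalSet:
        """Regions of one class; for sample_specific optionally one sample's."""
        picked = [
            iv
            for iv, c, s in zip(self.regions, self.classes, self.specific_sample)
            if c == cls and (sample_id is None or s == sample_id)
        ]
        return IntervalSet(picked)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for iv, occ, cls, spec in zip(
            self.regions, self.occupancy, self.classes, self.specific_sample
        ):
            row = {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "class": cls}
            row["specific_sample"] = spec if spec is not None else ""
            for s, present in zip(self.samples, occ):
                row[s] = bool(present)
            rows.append(row)
        return pd.DataFrame(rows)


def intersect_caller_peaks(
    peaks_caller1: IntervalSet, peaks_caller2: IntervalSet
) -> IntervalSet:
    """Caller-1 peaks that overlap (>=1 bp) at least one caller-2 peak.

    Caller-1 coordinates are retained — the intersection is a filter on peaks,
    not a geometric clip — preserving peak width information.
    """
    if len(peaks_caller1) == 0 or len(peaks_caller2) == 0:
        return IntervalSet()
    keep = overlapping_indices(peaks_caller1, peaks_caller2)
    return IntervalSet(peaks_caller1[i] for i in sorted(keep)).sort()


def qc_filter(
    counts: dict[str, int],
    factor: str,
    min_peaks: int = DEFAULT_MIN_PEAKS,
) -> QCReport:
    """Flag outlier samples by peak count for one factor.

    A sample is excluded when its count falls below the Tukey lower fence
    Q1 - 1.5*IQR (quantiles with linear interpolation over the factor's
    samples) or below ``min_peaks``. With a single sample the quantile rule
    cannot apply and only the hard floor is used (flagged with a warning).
    """
    values = np.array(list(counts.values()), dtype=float)
    fence: float | None = None
    warning = None
    if len(values) >= 2:
        q1, q3 = np.quantile(values, [0.25, 0.75])  # linear interpolation
        fence = float(q1 - 1.5 * (q3 - q1))
    else:
        warning = "single sample: quantile outlier rule skipped"
    records = []
    for sample_id, n in counts.items():
        reasons = []
        if fence is not None and n < fence:
            reasons.append(f"peak_count {n} < Q1-1.5*IQR fence {fence:.1f}")
        if n < min_peaks:
            reasons.append(f"peak_count {n} < min_peaks {min_peaks}")
        records.append(
            QCRecord(
                sample_id=sample_id,
                factor=factor,
                peak_count=int(n),
                excluded=bool(reasons),
                exclusion_reason="; ".join(reasons),
            )
        )
    return QCReport(records=records, fence=fence, warning=warning)


def build_membership(peak_sets: list[PeakSet]) -> MembershipTable:
    """Merged consensus regions x samples occupancy for one factor.

    Consensus regions are the gap-0 merge of all samples' peaks concatenated;
    occupancy(r, s) is true iff sample s has >=1 peak overlapping region r by
    >=1 bp.
    """
    if not peak_sets:
        raise ValueError("need at least one PeakSet")
    factors = {p.factor for p in peak_sets}
    if len(factors) > 1:
        raise ValueError(f"mixed factors in membership build: {sorted(factors)}")
    samples = [p.sample_id for p in peak_sets]
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids")
    all_peaks = IntervalSet(
        iv for p in peak_sets for iv in p.intervals
    )
    regions = merge_intervals(all_peaks, gap=0)
    occ = np.zeros((len(regions), len(samples)), dtype=bool)
    for j, p in enumerate(peak_sets):
        for ridx in overlapping_indices(regions, p.intervals):
            occ[ridx, j] = True
    return MembershipTable(regions=regions, samples=samples, occupancy=occ)


def pairwise_overlap_fraction(a: PeakSet, b: PeakSet) -> float | None:
    """Fraction of a's peaks overlapping >=1 peak of b (asymmetric).

    Returns None (missing) when a is empty.
    """
    if len(a.intervals) == 0:
        return None
    if len(b.intervals) == 0:
        return 0.0
    hits = overlapping_indices(a.intervals, b.intervals)
    return len(hits) / len(a.intervals)
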