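"""Genomic interval core types, interval algebra, and standard-format I/O.

Coordinates are BED-convention 0-based half-open throughout: an interval
[start, end) covers bases start .. end-1, and two intervals that merely abut
(a.end == b.start) do not overlap. Chromosome names are matched as exact
strings; no "chr" aliasing is performed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np


class BedParseError(ValueError):
    """Raised for malformed BED/chrom.sizes/GTF records, naming the line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open region on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """An ordered collection of genomic intervals.

    Tracks whether the collection is sorted by (chrom, start, end) and whether
    it is merged (no two same-chromosome intervals overlap).
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self.intervals: list[GenomicInterval] = list(intervals)
        self._update_flags()

    def _update_flags(self) -> None:
        ivs = self.intervals
        keys = [(iv.chrom, iv.start, iv.end) for iv in ivs]
        self.sorted = all(keys[i] <= keys[i + 1] for i in range(len(keys) - 1))
        merged = self.sorted
        if merged:
            for a, b in zip(ivs, ivs[1:]):
                if a.chrom == b.chrom and b.start < a.end:
                    merged = False
                    break
        self.merged = merged

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return (
            f"IntervalSet(n={len(self)}, sorted={self.sorted}, "
            f"merged={self.merged})"
        )

    def sort(self) -> "IntervalSet":
        """Return a new set sorted by (chrom, start, end)."""
        out = IntervalSet(
            sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        )
        return out

    def lengths(self) -> np.ndarray:
        return np.array([iv.length for iv in self.intervals], dtype=np.int64)

    def total_bp(self) -> int:
        """Total covered bases; counts overlapping bases multiply if unmerged."""
        return int(self.lengths().sum()) if len(self) else 0

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Map chrom -> array of (start, end, original_index), sorted by start."""
        groups: dict[str, list[tuple[int, int, int]]] = {}
        for i, iv in enumerate(self.intervals):
            groups.setdefault(iv.chrom, []).append((iv.start, iv.end, i))
        return {
            c: np.array(sorted(rows), dtype=np.int64) for c, rows in groups.items()
        }

    def validate_against(self, genome: "Genome") -> list[str]:
        """Return chromosome names absent from the genome (exact-string match)."""
        return [c for c in self.chroms() if c not in genome.chrom_sizes]


@dataclass
class Genome:
    """A genome assembly: chromosome sizes and, optionally, sequence."""

    chrom_sizes: dict[str, int]
    sequence: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c, n in self.chrom_sizes.items():
            if n <= 0:
                raise ValueError(f"chromosome {c} has non-positive length {n}")
        for c, seq in self.sequence.items():
            if c not in self.chrom_sizes:
                raise ValueError(f"sequence for unknown chromosome {c}")
            if len(seq) != self.chrom_sizes[c]:
                raise ValueError(
                    f"sequence length {len(seq)} != declared size "
                    f"{self.chrom_sizes[c]} for {c}"
                )

    @property
    def total_length(self) -> int:
        return sum(self.chrom_sizes.values())

    def fetch(self, iv: GenomicInterval) -> str:
        seq = self.sequence.get(iv.chrom)
        if seq is None:
            raise KeyError(f"no sequence loaded for chromosome {iv.chrom}")
        return seq[iv.start : iv.end]


@dataclass(frozen=True)
class Gene:
    """A gene reduced to what TSS-proximity analyses consume."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    start: int = -1
    end: int = -1


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------


def merge_intervals(s: IntervalSet, gap: int = 0) -> IntervalSet:
    """Union same-chromosome intervals separated by <= gap bases.

    The output is sorted and merged. With gap=0 the total covered bp is
    unchanged. Names and scores are dropped (merged regions are new entities).
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    if len(s) == 0:
        return IntervalSet()
    out: list[GenomicInterval] = []
    for iv in s.sort():
        if out and out[-1].chrom == iv.chrom and iv.start - out[-1].end <= gap:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return IntervalSet(out)


def overlap_query(
    a: IntervalSet, b: IntervalSet, min_bp: int = 1
) -> list[tuple[int, int]]:
    """All (index in a, index in b) pairs sharing >= min_bp bases.

    Sorted-sweep per chromosome; indices refer to the original input order.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    pairs: list[tuple[int, int]] = []
    b_by_chrom = b.by_chrom()
    for chrom, rows_a in a.by_chrom().items():
        rows_b = b_by_chrom.get(chrom)
        if rows_b is None:
            continue
        starts_b, ends_b = rows_b[:, 0], rows_b[:, 1]
        # candidate window: b intervals with start < a.end; check min_bp each
        for sa, ea, ia in rows_a:
            hi = int(np.searchsorted(starts_b, ea - min_bp, side="right"))
            for j in range(hi):
                ov = min(ea, ends_b[j]) - max(sa, starts_b[j])
                if ov >= min_bp:
                    pairs.append((int(ia), int(rows_b[j, 2])))
    pairs.sort()
    return pairs


def overlapping_indices(a: IntervalSet, b: IntervalSet, min_bp: int = 1) -> set[int]:
    """Indices of intervals in `a` overlapping at least one interval of `b`."""
    return {i for i, _ in overlap_query(a, b, min_bp=min_bp)}


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_SKIP_RE = re.compile(r"^(#|track\b|browser\b)")


def read_bed(path: str | Path) -> IntervalSet:
    """Read a BED3/BED6 file into an IntervalSet, order preserved.

    Comment, track and browser lines are skipped. Malformed lines raise
    :class:`BedParseError` naming the line number.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or _SKIP_RE.match(line):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: fewer than 3 fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end or start < 0:
                raise BedParseError(
                    f"{path}:{lineno}: invalid coordinates {start}-{end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: bad score") from exc
            intervals.append(GenomicInterval(chrom, start, end, name, score))
    return IntervalSet(intervals)


def write_bed(s: IntervalSet, path: str | Path, header: str | None = None) -> None:
    """Write BED; name/score columns emitted only when any interval has them."""
    has_name = any(iv.name is not None for iv in s)
    has_score = any(iv.score is not None for iv in s)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for iv in s:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if has_name or has_score:
                cols.append(iv.name if iv.name is not None else ".")
            if has_score:
                cols.append(f"{iv.score:g}" if iv.score is not None else ".")
            fh.write("\t".join(cols) + "\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read two-column chrom<TAB>size text."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 'chrom size'")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer size") from exc
    return sizes


def read_genome(
    chrom_sizes_path: str | Path, fasta_path: str | Path | None = None
) -> Genome:
    """Load a Genome from chrom.sizes, optionally attaching FASTA sequence."""
    sizes = read_chrom_sizes(chrom_sizes_path)
    sequence: dict[str, str] = {}
    if fasta_path is not None:
        from Bio import SeqIO

        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            sequence[rec.id] = str(rec.seq).upper()
    return Genome(chrom_sizes=sizes, sequence=sequence)


def write_fasta(sequence: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequence.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_genes_bed(path: str | Path) -> list[Gene]:
    """Genes from BED6: name = gene id, strand-aware TSS (start for +, end-1 for -)."""
    genes: list[Gene] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or _SKIP_RE.match(line):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise BedParseError(
                    f"{path}:{lineno}: gene BED requires 6 columns (id, strand)"
                )
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            gene_id, strand = fields[3], fields[5]
            if strand not in "+-":
                raise BedParseError(f"{path}:{lineno}: bad strand {strand!r}")
            tss = start if strand == "+" else end - 1
            genes.append(Gene(gene_id, chrom, tss, strand, start, end))
    _check_unique_gene_ids(genes, path)
    return genes


def read_genes_gtf(path: str | Path) -> list[Gene]:
    """Genes from GTF 'gene' features; only gene_id, TSS and strand are used."""
    genes: list[Gene] = []
    gid_re = re.compile(r'gene_id "([^"]+)"')
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise BedParseError(f"{path}:{lineno}: fewer than 9 GTF fields")
            if fields[2] != "gene":
                continue
            chrom, strand = fields[0], fields[6]
            start, end = int(fields[3]) - 1, int(fields[4])  # GTF is 1-based
            m = gid_re.search(fields[8])
            if m is None:
                raise BedParseError(f"{path}:{lineno}: missing gene_id attribute")
            tss = start if strand == "+" else end - 1
            genes.append(Gene(m.group(1), chrom, tss, strand, start, end))
    _check_unique_gene_ids(genes, path)
    return genes


def _check_unique_gene_ids(genes: Sequence[Gene], path: str | Path) -> None:
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise BedParseError(f"{path}: duplicate gene ids {dup[:5]}")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: name<TAB>description<TAB>gene1<TAB>gene2..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: GMT needs name, desc, genes")
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets
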