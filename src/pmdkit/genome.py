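"""Genome coordinate system and interval algebra.

All coordinates are 0-based, half-open (BED convention) throughout the
package; readers convert 1-based inputs at the boundary. Chromosome order is
the layout order (or first-appearance order when no layout is supplied) —
nothing here relies on lexicographic chromosome sorting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence


class CoordinateError(ValueError):
    """An interval falls outside its chromosome or is malformed."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise CoordinateError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and sizes (bp)."""

    chrom_names: tuple[str, ...]
    chrom_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(set(self.chrom_names)):
            raise ValueError("duplicate chromosome names")
        if len(self.chrom_names) != len(self.chrom_sizes):
            raise ValueError("names/sizes length mismatch")
        if any(s <= 0 for s in self.chrom_sizes):
            raise ValueError("chromosome sizes must be positive")

    @classmethod
    def from_dict(cls, sizes: dict[str, int]) -> "GenomeLayout":
        return cls(tuple(sizes), tuple(sizes.values()))

    @classmethod
    def from_file(cls, path: str | Path) -> "GenomeLayout":
        """Read a UCSC-style two-column chrom-sizes table."""
        names, sizes = [], []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            chrom, size = line.split("\t")[:2]
            names.append(chrom)
            sizes.append(int(size))
        return cls(tuple(names), tuple(sizes))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{c}\t{s}\n" for c, s in zip(self.chrom_names, self.chrom_sizes))
        )

    def size(self, chrom: str) -> int:
        try:
            return self.chrom_sizes[self.chrom_names.index(chrom)]
        except ValueError:
            raise CoordinateError(f"unknown chromosome {chrom!r}") from None

    def order(self, chrom: str) -> int:
        try:
            return self.chrom_names.index(chrom)
        except ValueError:
            raise CoordinateError(f"unknown chromosome {chrom!r}") from None

    def check(self, interval: GenomicInterval) -> None:
        if interval.end > self.size(interval.chrom):
            raise CoordinateError(
                f"{interval.chrom}:{interval.start}-{interval.end} exceeds "
                f"chromosome size {self.size(interval.chrom)}"
            )

    @property
    def total_size(self) -> int:
        return sum(self.chrom_sizes)


def _chrom_rank(intervals: Sequence[GenomicInterval], layout: Optional[GenomeLayout]):
    """Chromosome -> sort rank. Layout order if given, else first appearance."""
    if layout is not None:
        return {c: i for i, c in enumerate(layout.chrom_names)}
    rank: dict[str, int] = {}
    for iv in intervals:
        rank.setdefault(iv.chrom, len(rank))
    return rank


def sort_intervals(
    intervals: Sequence[GenomicInterval], layout: Optional[GenomeLayout] = None
) -> list[GenomicInterval]:
    rank = _chrom_rank(intervals, layout)
    return sorted(intervals, key=lambda iv: (rank[iv.chrom], iv.start, iv.end))


def merge_intervals(
    intervals: Sequence[GenomicInterval],
    max_gap: int = 0,
    layout: Optional[GenomeLayout] = None,
) -> list[GenomicInterval]:
    """Merge intervals whose gap is <= max_gap (bedtools `merge -d` semantics).

    Intervals separated by exactly max_gap bases are merged; different
    chromosomes never merge. Output is sorted and pairwise separated by
    gaps > max_gap.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if layout is not None:
        for iv in intervals:
            layout.check(iv)
    out: list[GenomicInterval] = []
    for iv in sort_intervals(intervals, layout):
        if out and out[-1].chrom == iv.chrom and iv.start - out[-1].end <= max_gap:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def subtract_intervals(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    layout: Optional[GenomeLayout] = None,
) -> list[GenomicInterval]:
    """Base-pair set difference a \\ b (bedtools subtract semantics)."""
    b_merged = merge_intervals(b, 0, layout)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in b_merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for iv in sort_intervals(a, layout):
        if layout is not None:
            layout.check(iv)
        cur = iv.start
        for cut in by_chrom.get(iv.chrom, ()):
            if cut.end <= cur or cut.start >= iv.end:
                continue
            if cut.start > cur:
                out.append(GenomicInterval(iv.chrom, cur, cut.start))
            cur = max(cur, cut.end)
            if cur >= iv.end:
                break
        if cur < iv.end:
            out.append(GenomicInterval(iv.chrom, cur, iv.end))
    return out


def intersect_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Base-pair intersection of two interval sets."""
    a_m = merge_intervals(a)
    b_m = merge_intervals(b)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in b_m:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = []
    for iv in a_m:
        for other in by_chrom.get(iv.chrom, ()):
            lo, hi = max(iv.start, other.start), min(iv.end, other.end)
            if lo < hi:
                out.append(GenomicInterval(iv.chrom, lo, hi))
    return out


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(iv.length for iv in intervals)


def jaccard(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> float:
    """Base-pair Jaccard index: |a ∩ b| / |a ∪ b|. Undefined for two empty sets."""
    inter = total_length(intersect_intervals(a, b))
    union = (
        total_length(merge_intervals(a))
        + total_length(merge_intervals(b))
        - inter
    )
    if union == 0:
        raise ValueError("jaccard undefined: both interval sets are empty")
    return inter / union


def make_windows(layout: GenomeLayout, size: int) -> list[GenomicInterval]:
    """Tile every chromosome with fixed-width windows; last window truncated."""
    if size <= 0:
        raise ValueError("window size must be positive")
    out = []
    for chrom, length in zip(layout.chrom_names, layout.chrom_sizes):
        for start in range(0, length, size):
            out.append(GenomicInterval(chrom, start, min(start + size, length)))
    return out


@dataclass(frozen=True)
class ExclusionSet:
    """Unmappable regions (assembly gaps, centromeres) masked from all calls.

    Intervals are sorted and non-overlapping after construction. `build`
    merges the raw annotation intervals with a configurable gap — the domain
    callers expect gap and centromere annotations pooled and merged with a
    10 Mb slack so that entire pericentromeric blocks are excised in one piece.
    """

    intervals: tuple[GenomicInterval, ...] = field(default=())

    @classmethod
    def build(
        cls,
        intervals: Sequence[GenomicInterval],
        merge_gap: int = 10_000_000,
        layout: Optional[GenomeLayout] = None,
    ) -> "ExclusionSet":
        return cls(tuple(merge_intervals(intervals, merge_gap, layout)))

    @classmethod
    def empty(cls) -> "ExclusionSet":
        return cls(())

    def for_chrom(self, chrom: str) -> list[GenomicInterval]:
        return [iv for iv in self.intervals if iv.chrom == chrom]


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read the first three columns of a BED file (no header)."""
    out = []
    for line in _read_lines(path):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return out


def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    names: Optional[Sequence[str]] = None,
) -> None:
    """Write BED3, or BED4 when per-interval names are given."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            if names is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{names[i]}\n")


def read_bed4(path: str | Path) -> tuple[list[GenomicInterval], list[str]]:
    """Read BED with a name column; returns (intervals, names)."""
    ivs, names = [], []
    for line in _read_lines(path):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        ivs.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
        names.append(fields[3] if len(fields) > 3 else "")
    return ivs, names


def _read_lines(path: str | Path) -> list[str]:
    import gzip

    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            return fh.readlines()
    return path.read_text().splitlines()
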