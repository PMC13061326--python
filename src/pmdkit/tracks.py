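"""Methylation and coverage track I/O plus weighted window/domain summaries.

CpG-resolution methylation is held as (chrom, pos, meth_reads, total_reads)
records; binned signal as a `BinnedTrack` of uniform windows with one float
per window (NaN = missing). Weighted mean methylation over an interval is
100 * sum(meth) / sum(total) across contained CpGs — read-count weighted, the
standard WGBS domain summary.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .genome import GenomeLayout, GenomicInterval, make_windows

log = logging.getLogger(__name__)


class CpGRecord(NamedTuple):
    chrom: str
    pos: int
    meth_reads: int
    total_reads: int


class ParseError(ValueError):
    pass


@dataclass
class BinnedTrack:
    """Fixed-width genomic windows with one value per window.

    Windows are sorted, grouped by chromosome, non-overlapping and of uniform
    width except at chromosome ends. `values` is float with NaN for missing.
    """

    windows: list[GenomicInterval]
    values: np.ndarray
    bin_size: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.windows) != len(self.values):
            raise ValueError("windows/values length mismatch")

    @classmethod
    def from_layout(
        cls, layout: GenomeLayout, bin_size: int, values=None
    ) -> "BinnedTrack":
        windows = make_windows(layout, bin_size)
        if values is None:
            values = np.full(len(windows), np.nan)
        return cls(windows, values, bin_size)

    def same_grid(self, other: "BinnedTrack") -> bool:
        return self.bin_size == other.bin_size and self.windows == other.windows

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous index range per chromosome (windows are chrom-grouped)."""
        out: dict[str, slice] = {}
        i = 0
        while i < len(self.windows):
            chrom = self.windows[i].chrom
            j = i
            while j < len(self.windows) and self.windows[j].chrom == chrom:
                j += 1
            out[chrom] = slice(i, j)
            i = j
        return out

    def with_values(self, values) -> "BinnedTrack":
        return BinnedTrack(self.windows, np.asarray(values, dtype=float), self.bin_size)

    def midpoints(self) -> np.ndarray:
        return np.array([(w.start + w.end) / 2.0 for w in self.windows])

    def to_bedgraph(self, path: str | Path, fmt: str = "%.6g") -> None:
        with _open_write(path) as fh:
            for w, v in zip(self.windows, self.values):
                if np.isnan(v):
                    continue
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{fmt % v}\n")

    @classmethod
    def from_bedgraph(
        cls, path: str | Path, layout: GenomeLayout, bin_size: int
    ) -> "BinnedTrack":
        """Load a bedGraph onto the layout's uniform grid; absent windows NaN."""
        track = cls.from_layout(layout, bin_size)
        index = {(w.chrom, w.start): i for i, w in enumerate(track.windows)}
        for ln, line in enumerate(_read_lines(path), 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            try:
                key = (f[0], int(f[1]))
                val = float(f[3])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}: malformed line {ln}: {line!r}") from exc
            if key not in index:
                raise ParseError(
                    f"{path}: line {ln} does not start on the {bin_size} bp grid"
                )
            track.values[index[key]] = val
        return track


def _open_write(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "wt")
    return open(path, "w")


def _read_lines(path: str | Path) -> list[str]:
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            return fh.readlines()
    return path.read_text().splitlines()


def read_methylation(path: str | Path, format: str = "bismark-cov") -> list[CpGRecord]:
    """Read per-CpG methylation calls.

    ``bismark-cov``: chrom, start, end, %meth, count_meth, count_unmeth.
    The CpG position is taken as ``end - 1``, which handles both the 1-based
    inclusive convention (start == end) and 0-based half-open exports
    (end == start + 1) identically.

    ``bedgraph``: chrom, start, end, %meth, coverage — percent converted back
    to read counts (meth = round(pct * cov / 100)).

    Records are returned sorted by (chrom first-appearance, pos).
    """
    if format not in ("bismark-cov", "bedgraph"):
        raise ValueError(f"unknown methylation format {format!r}")
    records: list[CpGRecord] = []
    for ln, line in enumerate(_read_lines(path), 1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.rstrip("\n").split("\t")
        try:
            if format == "bismark-cov":
                chrom, _, end = f[0], int(f[1]), int(f[2])
                meth, unmeth = int(f[4]), int(f[5])
                rec = CpGRecord(chrom, end - 1, meth, meth + unmeth)
            else:
                chrom, _, end, pct, cov = f[0], int(f[1]), int(f[2]), float(f[3]), int(f[4])
                rec = CpGRecord(chrom, end - 1, int(round(pct * cov / 100.0)), cov)
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{path}: malformed line {ln}: {line!r}") from exc
        if rec.meth_reads > rec.total_reads or rec.total_reads < 1:
            raise ParseError(
                f"{path}: line {ln}: methylated reads exceed total "
                f"({rec.meth_reads}/{rec.total_reads})"
            )
        records.append(rec)
    order: dict[str, int] = {}
    for r in records:
        order.setdefault(r.chrom, len(order))
    records.sort(key=lambda r: (order[r.chrom], r.pos))
    return records


def write_methylation(
    records: Sequence[CpGRecord], path: str | Path, format: str = "bismark-cov"
) -> None:
    """Write per-CpG calls in 0-based half-open coordinates (pos, pos+1)."""
    with _open_write(path) as fh:
        for r in records:
            pct = 100.0 * r.meth_reads / r.total_reads
            if format == "bismark-cov":
                fh.write(
                    f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{pct:.6g}\t"
                    f"{r.meth_reads}\t{r.total_reads - r.meth_reads}\n"
                )
            elif format == "bedgraph":
                fh.write(
                    f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{pct:.6g}\t{r.total_reads}\n"
                )
            else:
                raise ValueError(f"unknown methylation format {format!r}")


def _cpg_arrays(records: Sequence[CpGRecord]):
    """Per-chromosome (pos, cum_meth, cum_total) arrays from sorted records."""
    out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    i = 0
    n = len(records)
    while i < n:
        chrom = records[i].chrom
        j = i
        while j < n and records[j].chrom == chrom:
            j += 1
        pos = np.fromiter((records[k].pos for k in range(i, j)), dtype=np.int64)
        meth = np.fromiter((records[k].meth_reads for k in range(i, j)), dtype=np.int64)
        tot = np.fromiter((records[k].total_reads for k in range(i, j)), dtype=np.int64)
        out[chrom] = (pos, np.concatenate([[0], meth.cumsum()]),
                      np.concatenate([[0], tot.cumsum()]))
        i = j
    return out


def weighted_mean_methylation(
    records: Sequence[CpGRecord],
    intervals: Sequence[GenomicInterval],
    min_coverage: int = 1,
) -> np.ndarray:
    """Read-weighted % methylation per interval; NaN when no qualifying CpG.

    Per interval: 100 * sum(meth_reads) / sum(total_reads) over contained CpGs
    with total_reads >= min_coverage. Records must be position-sorted within
    chromosomes (as read_methylation returns them).
    """
    kept = [r for r in records if r.total_reads >= min_coverage]
    arrays = _cpg_arrays(kept)
    out = np.full(len(intervals), np.nan)
    for i, iv in enumerate(intervals):
        if iv.chrom not in arrays:
            continue
        pos, cmeth, ctot = arrays[iv.chrom]
        lo = np.searchsorted(pos, iv.start, side="left")
        hi = np.searchsorted(pos, iv.end, side="left")
        tot = ctot[hi] - ctot[lo]
        if tot > 0:
            out[i] = 100.0 * (cmeth[hi] - cmeth[lo]) / tot
    return out


def methylation_track(
    records: Sequence[CpGRecord],
    layout: GenomeLayout,
    bin_size: int = 10_000,
    min_coverage: int = 1,
) -> BinnedTrack:
    """Window-mean methylation track over a uniform grid."""
    track = BinnedTrack.from_layout(layout, bin_size)
    track.values = weighted_mean_methylation(records, track.windows, min_coverage)
    return track


def bin_counts(
    fragments: Sequence[GenomicInterval],
    windows: Sequence[GenomicInterval],
) -> BinnedTrack:
    """Overlap counts per window (bedtools `coverage -counts` semantics).

    A fragment is counted in every window it overlaps, so a fragment spanning
    a window boundary increments both windows. Windows must be sorted and
    non-overlapping within chromosomes.
    """
    counts = np.zeros(len(windows), dtype=float)
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    offset: dict[str, int] = {}
    i = 0
    while i < len(windows):
        chrom = windows[i].chrom
        j = i
        while j < len(windows) and windows[j].chrom == chrom:
            j += 1
        starts[chrom] = np.array([w.start for w in windows[i:j]])
        ends[chrom] = np.array([w.end for w in windows[i:j]])
        offset[chrom] = i
        i = j
    for frag in fragments:
        if frag.chrom not in starts:
            continue
        s, e, off = starts[frag.chrom], ends[frag.chrom], offset[frag.chrom]
        lo = np.searchsorted(e, frag.start, side="right")
        hi = np.searchsorted(s, frag.end, side="left")
        if hi > lo:
            counts[off + lo : off + hi] += 1
    bin_size = max(w.length for w in windows) if windows else 0
    return BinnedTrack(list(windows), counts, bin_size)


def interval_means(
    track: BinnedTrack, intervals: Sequence[GenomicInterval]
) -> np.ndarray:
    """Overlap-weighted mean of a binned track over arbitrary intervals.

    NaN windows are ignored; an interval covering only NaN windows is NaN.
    """
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    vals: dict[str, np.ndarray] = {}
    i = 0
    w = track.windows
    while i < len(w):
        chrom = w[i].chrom
        j = i
        while j < len(w) and w[j].chrom == chrom:
            j += 1
        starts[chrom] = np.array([x.start for x in w[i:j]])
        ends[chrom] = np.array([x.end for x in w[i:j]])
        vals[chrom] = track.values[i:j]
        i = j
    out = np.full(len(intervals), np.nan)
    for k, iv in enumerate(intervals):
        if iv.chrom not in starts:
            continue
        s, e, v = starts[iv.chrom], ends[iv.chrom], vals[iv.chrom]
        lo = np.searchsorted(e, iv.start, side="right")
        hi = np.searchsorted(s, iv.end, side="left")
        if hi <= lo:
            continue
        overlap = np.minimum(e[lo:hi], iv.end) - np.maximum(s[lo:hi], iv.start)
        vv = v[lo:hi]
        mask = ~np.isnan(vv)
        if overlap[mask].sum() > 0:
            out[k] = np.average(vv[mask], weights=overlap[mask])
    return out
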