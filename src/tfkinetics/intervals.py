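"""Genomic intervals: container, text-format I/O, and a small sorted-array engine.

Coordinates are 0-based half-open throughout the package; the only 1-based
boundary is the methylation TSV reader/writer. Peak files are plain BED3/BED6/
narrowPeak text and coverage is bedGraph, so no binary index is ever needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "read_intervals",
    "write_bed",
    "write_bedgraph",
    "read_bedgraph",
    "overlap_bp",
    "merge_intervals",
    "IntervalIndex",
]


class IntervalFormatError(ValueError):
    """Raised for malformed interval files; message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on `chrom`."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float = 0.0
    name: str = "."
    meta: dict = field(default_factory=dict, compare=False, hash=False)

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Shared bases between two half-open intervals (0 if different chroms)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


_FORMATS = {"BED3", "BED6", "narrowPeak", "bedGraph"}


def read_intervals(path, format: str = "BED6") -> list[GenomicInterval]:
    """Read intervals from a BED-family text file, in file order.

    narrowPeak keeps the point-source summit offset in ``meta['summit']``
    (absolute coordinate ``start + offset``; -1 offsets are dropped).
    bedGraph stores the fourth column as ``score``.
    """
    if format not in _FORMATS:
        raise ValueError(f"unsupported format {format!r}; expected one of {sorted(_FORMATS)}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except (IndexError, ValueError) as exc:
                raise IntervalFormatError(f"{path}: malformed line {lineno}: {line!r}") from exc
            if start >= end:
                raise IntervalFormatError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            name, score, strand, meta = ".", 0.0, ".", {}
            if format == "bedGraph":
                if len(fields) < 4:
                    raise IntervalFormatError(f"{path}: malformed bedGraph line {lineno}")
                score = float(fields[3])
            else:
                if len(fields) >= 4:
                    name = fields[3]
                if len(fields) >= 5 and fields[4] != ".":
                    score = float(fields[4])
                if len(fields) >= 6:
                    strand = fields[5]
            if format == "narrowPeak":
                if len(fields) < 10:
                    raise IntervalFormatError(
                        f"{path}: line {lineno}: narrowPeak requires 10 columns"
                    )
                meta = {
                    "signalValue": float(fields[6]),
                    "pValue": float(fields[7]),
                    "qValue": float(fields[8]),
                }
                offset = int(fields[9])
                if offset >= 0:
                    meta["summit"] = start + offset
            out.append(
                GenomicInterval(chrom, start, end, strand=strand, score=score,
                                name=name, meta=meta)
            )
    return out


def write_bed(intervals: Iterable[GenomicInterval], path, columns: int = 6) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for iv in intervals:
            row = [iv.chrom, str(iv.start), str(iv.end)]
            if columns >= 6:
                row += [iv.name, f"{iv.score:g}", iv.strand]
            fh.write("\t".join(row) + "\n")


def write_bedgraph(chrom_values: dict[str, np.ndarray], path) -> None:
    """Write dense per-base values as run-length-compressed bedGraph (zeros skipped)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for chrom in sorted(chrom_values):
            vals = np.asarray(chrom_values[chrom])
            if vals.size == 0:
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [vals.size]])
            for s, e in zip(starts, ends):
                v = vals[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_bedgraph(path, chrom_sizes: dict[str, int]) -> dict[str, np.ndarray]:
    """Expand a bedGraph into dense per-base float arrays."""
    out = {c: np.zeros(n) for c, n in chrom_sizes.items()}
    for iv in read_intervals(path, format="bedGraph"):
        if iv.chrom in out:
            out[iv.chrom][iv.start: iv.end] = iv.score
    return out


def merge_intervals(
    intervals: Sequence[GenomicInterval], gap_bp: int = 0
) -> list[GenomicInterval]:
    """Merge intervals that overlap or lie within ``gap_bp`` of each other.

    With ``gap_bp == 0`` only true overlaps (>= 1 shared base) merge; touching
    half-open intervals stay separate. Output is sorted by (chrom, start);
    merged intervals keep the max score.
    """
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and (
                iv.start < merged[-1].end
                or (gap_bp > 0 and iv.start - merged[-1].end <= gap_bp)
            )
        ):
            prev = merged[-1]
            merged[-1] = replace(
                prev,
                end=max(prev.end, iv.end),
                score=max(prev.score, iv.score),
            )
        else:
            merged.append(replace(iv, meta=dict(iv.meta)))
    return merged


class IntervalIndex:
    """Sorted-array overlap/containment queries over a fixed interval set.

    Intervals are stored per chromosome as parallel start/end arrays sorted by
    start. Because the catalogs this package builds are merged (non-nested),
    binary search over starts plus a linear walk is exact and fast enough for
    toy-genome scale; correctness is checked against a quadratic oracle in the
    test suite.
    """

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self.intervals = list(intervals)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        by_chrom: dict[str, list[int]] = {}
        for i, iv in enumerate(self.intervals):
            by_chrom.setdefault(iv.chrom, []).append(i)
        for chrom, idxs in by_chrom.items():
            idxs = sorted(idxs, key=lambda i: self.intervals[i].start)
            starts = np.array([self.intervals[i].start for i in idxs])
            ends = np.array([self.intervals[i].end for i in idxs])
            cummax_end = np.maximum.accumulate(ends)
            self._by_chrom[chrom] = (starts, ends, np.array(idxs), cummax_end)

    def __len__(self) -> int:
        return len(self.intervals)

    def overlapping(self, chrom: str, start: int, end: int,
                    min_overlap_bp: int = 1) -> list[int]:
        """Indices of stored intervals sharing >= min_overlap_bp bases with [start, end)."""
        if chrom not in self._by_chrom:
            return []
        starts, ends, idxs, cummax_end = self._by_chrom[chrom]
        hits = []
        # candidates start before `end`; prefix-max of ends prunes the left edge
        # (everything before `lo` ends at or before `start`).
        hi = int(np.searchsorted(starts, end, side="left"))
        lo = int(np.searchsorted(cummax_end, start, side="right"))
        for j in range(lo, hi):
            ov = min(ends[j], end) - max(starts[j], start)
            if ov >= min_overlap_bp:
                hits.append(int(idxs[j]))
        return hits

    def any_overlap(self, chrom: str, start: int, end: int,
                    min_overlap_bp: int = 1) -> bool:
        return bool(self.overlapping(chrom, start, end, min_overlap_bp))

    def containing_point(self, chrom: str, pos: int) -> list[int]:
        """Indices of stored intervals with start <= pos < end."""
        return self.overlapping(chrom, pos, pos + 1)
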