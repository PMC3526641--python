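"""Genome interval bookkeeping: a small BED6-backed interval model.

All coordinates are 0-based, half-open (BED convention), everywhere.
The interval ``name`` column carries ``category|identifier`` so that a
single BED file can hold a mixed annotation track.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Interval",
    "read_bed",
    "write_bed",
    "write_gff3",
    "merge_spans",
    "covered_bases",
    "IntervalIndex",
]


@dataclass(frozen=True)
class Interval:
    """One annotated genome interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    name: str
    strand: str
    category: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"degenerate interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def write_bed(intervals: Iterable[Interval], path: str) -> None:
    """Write intervals as BED6 with name = ``category|name``."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{iv.category}|{iv.name}\t0\t{iv.strand}\n"
            )


def read_bed(path: str) -> list[Interval]:
    out: list[Interval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: expected BED6, got {len(parts)} columns")
            chrom, start, end, name, _score, strand = parts[:6]
            if "|" in name:
                category, ident = name.split("|", 1)
            else:
                category, ident = name, name
            out.append(Interval(chrom, int(start), int(end), ident, strand, category))
    return out


def write_gff3(intervals: Iterable[Interval], path: str, source: str = "srnakit") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{source}\t{iv.category}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={iv.name};category={iv.category}\n"
            )


def merge_spans(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open spans into a sorted disjoint list."""
    spans = sorted(spans)
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def covered_bases(merged: Sequence[tuple[int, int]], start: int, end: int) -> int:
    """Bases of [start, end) covered by a *merged* disjoint span list.

    Uses prefix sums over the merged boundaries so window queries are
    O(log n) rather than per-base.
    """
    if not merged or end <= start:
        return 0
    starts = [s for s, _ in merged]
    total = 0
    i = bisect.bisect_right(starts, start) - 1
    if i < 0:
        i = 0
    for s, e in merged[i:]:
        if s >= end:
            break
        lo, hi = max(s, start), min(e, end)
        if hi > lo:
            total += hi - lo
    return total


class IntervalIndex:
    """Per-chromosome vectorized overlap queries over a fixed interval set."""

    def __init__(self, intervals: Iterable[Interval]):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, list[Interval]]] = {}
        grouped: dict[str, list[Interval]] = {}
        for iv in intervals:
            grouped.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in grouped.items():
            ivs = sorted(ivs, key=lambda v: (v.start, v.end))
            starts = np.array([v.start for v in ivs], dtype=np.int64)
            ends = np.array([v.end for v in ivs], dtype=np.int64)
            strands = np.array([v.strand == "+" for v in ivs], dtype=bool)
            self._by_chrom[chrom] = (starts, ends, strands, ivs)

    def overlapping(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> list[Interval]:
        """Intervals with >=1 nt intersection with [start, end).

        ``strand``: restrict to same-strand features; None = strand-agnostic.
        """
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        starts, ends, strands, ivs = entry
        mask = (starts < end) & (ends > start)
        if strand is not None:
            mask &= strands == (strand == "+")
        return [ivs[i] for i in np.nonzero(mask)[0]]
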