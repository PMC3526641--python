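"""Read cleaning and collapsing into unique families.

Cleaning removes the 3' adapter (>=8 nt exact prefix match), then drops
reads in this fixed order: contaminants (empty insert after trimming, or
any N in the insert), low mean quality, and finally length outside the
selection window.  The report always balances:
``n_raw == n_clean + sum(discards)``.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._io import FastqRead, parse_fastq

__all__ = [
    "CleaningReport",
    "UniqueRead",
    "clean_reads",
    "collapse_unique",
    "merge_libraries",
    "write_collapsed_fasta",
    "read_collapsed_fasta",
]

MAIN_WINDOW = (18, 30)      # library size selection window
RASIRNA_WINDOW = (23, 32)   # applied downstream as a filter, not a re-clean


@dataclass
class CleaningReport:
    n_raw: int = 0
    n_discarded_low_quality: int = 0
    n_discarded_contaminant: int = 0
    n_discarded_length: int = 0
    n_clean: int = 0
    length_histogram: dict[int, int] = field(default_factory=dict)

    def check_balance(self) -> None:
        total = (
            self.n_clean
            + self.n_discarded_low_quality
            + self.n_discarded_contaminant
            + self.n_discarded_length
        )
        if total != self.n_raw:
            raise AssertionError(f"cleaning report does not balance: {self}")
        if sum(self.length_histogram.values()) != self.n_clean:
            raise AssertionError("length histogram does not sum to n_clean")

    def to_json(self) -> str:
        d = self.__dict__.copy()
        d["length_histogram"] = {str(k): v for k, v in sorted(self.length_histogram.items())}
        return json.dumps(d, indent=2)


@dataclass
class UniqueRead:
    """A unique family: one distinct sequence with per-library copy counts."""

    sequence: str
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _mean_quality(qual: str) -> float:
    arr = np.frombuffer(qual.encode(), dtype=np.uint8).astype(float) - 33
    return float(arr.mean()) if arr.size else 0.0


def clean_reads(
    reads: Iterable[FastqRead] | str,
    adapter: str,
    min_len: int = MAIN_WINDOW[0],
    max_len: int = MAIN_WINDOW[1],
    quality_floor: float = 20.0,
    adapter_seed: int = 8,
) -> tuple[list[str], CleaningReport]:
    """Clean a FASTQ stream (or path); return clean insert sequences + report.

    A read with no adapter hit is kept untrimmed if it already falls in
    the length window.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    if isinstance(reads, str):
        reads = parse_fastq(reads)
    seed = adapter[:adapter_seed]
    report = CleaningReport()
    hist: Counter[int] = Counter()
    clean: list[str] = []
    for read in reads:
        report.n_raw += 1
        pos = read.sequence.find(seed) if seed else -1
        if pos >= 0:
            insert, qual = read.sequence[:pos], read.quality[:pos]
        else:
            insert, qual = read.sequence, read.quality
        if not insert or "N" in insert:
            report.n_discarded_contaminant += 1
            continue
        if _mean_quality(qual) < quality_floor:
            report.n_discarded_low_quality += 1
            continue
        if not min_len <= len(insert) <= max_len:
            report.n_discarded_length += 1
            continue
        clean.append(insert)
        hist[len(insert)] += 1
    report.n_clean = len(clean)
    report.length_histogram = dict(sorted(hist.items()))
    report.check_balance()
    return clean, report


def collapse_unique(clean: Sequence[str], library_label: str) -> list[UniqueRead]:
    """Cluster identical reads into unique families.

    Output order is deterministic: descending count, then lexicographic.
    """
    tally = Counter(clean)
    return [
        UniqueRead(seq, {library_label: n})
        for seq, n in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def merge_libraries(collections: Iterable[Sequence[UniqueRead]]) -> list[UniqueRead]:
    """Merge per-library unique families into one multi-library collection."""
    merged: dict[str, dict[str, int]] = {}
    for coll in collections:
        for ur in coll:
            counts = merged.setdefault(ur.sequence, {})
            for lib, n in ur.counts.items():
                counts[lib] = counts.get(lib, 0) + n
    out = [UniqueRead(seq, counts) for seq, counts in merged.items()]
    out.sort(key=lambda ur: (-ur.total, ur.sequence))
    return out


def write_collapsed_fasta(uniques: Sequence[UniqueRead], path: str) -> None:
    """Write families as ``>u<idx>_<total> [lib=count ...]`` FASTA."""
    with open(path, "w") as fh:
        for i, ur in enumerate(uniques):
            libs = ";".join(f"{lib}={n}" for lib, n in sorted(ur.counts.items()))
            fh.write(f">u{i}_{ur.total} {libs}\n{ur.sequence}\n")


def read_collapsed_fasta(path: str) -> list[UniqueRead]:
    out: list[UniqueRead] = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                header = line[1:]
            elif line:
                parts = header.split(None, 1)
                counts: dict[str, int] = {}
                if len(parts) == 2:
                    for item in parts[1].split(";"):
                        lib, n = item.split("=")
                        counts[lib] = int(n)
                else:
                    counts["lib"] = int(parts[0].rsplit("_", 1)[1])
                out.append(UniqueRead(line, counts))
    return out
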