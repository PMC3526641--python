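"""Exact multimapping and the annotation priority cascade.

Mapping is exact (0 mismatches) on both strands and reports *all* loci;
minus-strand hits are reported in plus-strand coordinates of the matched
substring.  Each unique read then receives exactly one category: the
highest-priority category among the features overlapped by any of its
hits.  ncRNA/miRNA overlap requires the same strand; repeat and exon
overlap is strand-agnostic (repeat-derived small RNAs arise from both
strands).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._intervals import Interval, IntervalIndex
from ._io import revcomp
from .preprocess import UniqueRead

__all__ = [
    "Hit",
    "AnnotatedRead",
    "GenomeIndex",
    "map_exact",
    "AnnotationTracks",
    "annotate_cascade",
    "annotate_all",
    "category_table",
    "DEFAULT_PRIORITY",
    "CASCADE_CATEGORIES",
]

#: Highest first. Configurable via the ``priority`` arguments below.
DEFAULT_PRIORITY = (
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "miRNA",
    "repeat:LINE",
    "repeat:LTR",
    "repeat:satellite",
    "repeat:other",
    "exon",
    "intron",
)

CASCADE_CATEGORIES = DEFAULT_PRIORITY + ("unannotated", "unmapped")

#: Categories whose overlap test requires the read hit on the same strand.
_STRANDED = frozenset({"rRNA", "tRNA", "snRNA", "snoRNA", "miRNA"})

#: Track-vocabulary -> cascade-vocabulary renames.
TRACK_TO_CASCADE = {
    "miRNA_hairpin": "miRNA",
    "LINE": "repeat:LINE",
    "LTR": "repeat:LTR",
    "satellite": "repeat:satellite",
    "other_repeat": "repeat:other",
}


@dataclass(frozen=True, order=True)
class Hit:
    chrom: str
    start: int
    strand: str
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length

    def five_prime(self) -> int:
        """Genome coordinate of the read's 5' end (strand-aware)."""
        return self.start if self.strand == "+" else self.start + self.length - 1


@dataclass
class AnnotatedRead:
    unique_read: UniqueRead
    hits: list[Hit]
    category: str

    @property
    def n_loci(self) -> int:
        return len(self.hits)

    @property
    def sequence(self) -> str:
        return self.unique_read.sequence

    @property
    def total(self) -> int:
        return self.unique_read.total


class GenomeIndex:
    """Seeded exact matcher: k-mer prefix index plus full verification.

    Reads shorter than the seed length fall back to a full text scan and
    are never silently dropped.
    """

    def __init__(self, genome: dict[str, str], k: int = 18):
        self.genome = genome
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.items():
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((chrom, i))

    def _seeded(self, query: str) -> Iterable[tuple[str, int]]:
        for chrom, pos in self._index.get(query[: self.k], ()):
            if self.genome[chrom].startswith(query, pos):
                yield chrom, pos

    def _scan(self, query: str) -> Iterable[tuple[str, int]]:
        for chrom, seq in self.genome.items():
            pos = seq.find(query)
            while pos != -1:
                yield chrom, pos
                pos = seq.find(query, pos + 1)

    def find_all(self, read: str) -> list[Hit]:
        """All exact-match loci of ``read`` on both strands, sorted."""
        n = len(read)
        finder = self._seeded if n >= self.k else self._scan
        hits = [Hit(c, p, "+", n) for c, p in finder(read)]
        rc = revcomp(read)
        hits += [Hit(c, p, "-", n) for c, p in finder(rc)]
        return sorted(hits)


def map_exact(
    unique_reads: Sequence[UniqueRead], genome: dict[str, str] | GenomeIndex
) -> list[list[Hit]]:
    """Map each unique read to all exact loci; parallel list of hit lists."""
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    return [index.find_all(ur.sequence) for ur in unique_reads]


class AnnotationTracks:
    """Per-category interval indexes in cascade vocabulary."""

    def __init__(self, intervals: Iterable[Interval], priority: Sequence[str] = DEFAULT_PRIORITY):
        self.priority = tuple(priority)
        by_cat: dict[str, list[Interval]] = {}
        for iv in intervals:
            cat = TRACK_TO_CASCADE.get(iv.category, iv.category)
            if cat == "miRNA_mature":
                continue  # used by the miRNA profiler, not the cascade
            if cat not in self.priority:
                raise ValueError(f"unknown category in track: {iv.category!r}")
            by_cat.setdefault(cat, []).append(iv)
        # sort within category so track file order never matters
        self._index = {
            cat: IntervalIndex(sorted(ivs, key=lambda v: (v.chrom, v.start, v.end, v.name)))
            for cat, ivs in by_cat.items()
        }

    def categories_at(self, hit: Hit) -> set[str]:
        found = set()
        for cat, idx in self._index.items():
            strand = hit.strand if cat in _STRANDED else None
            if idx.overlapping(hit.chrom, hit.start, hit.end, strand):
                found.add(cat)
        return found


def annotate_cascade(
    read: UniqueRead,
    hits: Sequence[Hit],
    tracks: AnnotationTracks,
    priority: Sequence[str] | None = None,
) -> AnnotatedRead:
    """Assign one category from the union of all hit overlaps."""
    priority = tuple(priority) if priority is not None else tracks.priority
    if not hits:
        return AnnotatedRead(read, [], "unmapped")
    overlapped: set[str] = set()
    for hit in hits:
        overlapped |= tracks.categories_at(hit)
    for cat in priority:
        if cat in overlapped:
            return AnnotatedRead(read, list(hits), cat)
    return AnnotatedRead(read, list(hits), "unannotated")


def annotate_all(
    unique_reads: Sequence[UniqueRead],
    genome: dict[str, str] | GenomeIndex,
    tracks: AnnotationTracks,
    priority: Sequence[str] | None = None,
) -> list[AnnotatedRead]:
    hit_lists = map_exact(unique_reads, genome)
    return [
        annotate_cascade(ur, hits, tracks, priority)
        for ur, hits in zip(unique_reads, hit_lists)
    ]


def category_table(annotated: Sequence[AnnotatedRead]) -> pd.DataFrame:
    """Per-category unique-read and copy counts with fractions.

    Fractions sum to 1 separately for unique reads and for copies; an
    empty input yields an empty table.
    """
    rows = {}
    for ar in annotated:
        entry = rows.setdefault(ar.category, [0, 0])
        entry[0] += 1
        entry[1] += ar.unique_read.total
    if not rows:
        return pd.DataFrame(
            columns=["category", "n_unique", "n_copies", "frac_unique", "frac_copies"]
        )
    df = pd.DataFrame(
        [(cat, u, c) for cat, (u, c) in rows.items()],
        columns=["category", "n_unique", "n_copies"],
    )
    order = {cat: i for i, cat in enumerate(CASCADE_CATEGORIES)}
    df = df.sort_values("category", key=lambda s: s.map(order)).reset_index(drop=True)
    df["frac_unique"] = df["n_unique"] / df["n_unique"].sum()
    df["frac_copies"] = df["n_copies"] / df["n_copies"].sum()
    return df


def write_annotated_tsv(annotated: Sequence[AnnotatedRead], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tcounts\tn_loci\tcategory\thits\n")
        for ar in annotated:
            counts = ";".join(f"{lib}={n}" for lib, n in sorted(ar.unique_read.counts.items()))
            hits = ";".join(f"{h.chrom}:{h.start}:{h.strand}:{h.length}" for h in ar.hits)
            fh.write(f"{ar.sequence}\t{counts}\t{ar.n_loci}\t{ar.category}\t{hits}\n")
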