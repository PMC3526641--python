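"""rasiRNA-like read selection and characterization.

Candidates are unannotated unique reads of 23-32 nt mapping to 1-5
discrete loci.  Characterization covers the positional base composition
(5'-U bias), chromosome-length-normalized distribution, and
strand-resolved sliding-window densities.  Multi-locus reads contribute
1/n_loci per hit so nothing is double counted; a read belongs to a
window by its 5' end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._intervals import Interval, covered_bases, merge_spans
from .annotate import AnnotatedRead

__all__ = [
    "select_rasirna_candidates",
    "fivep_bias",
    "chrom_distribution",
    "feature_density",
    "read_density",
    "DensityTrack",
    "write_bedgraph",
]

LENGTH_WINDOW = (23, 32)
MAX_LOCI = 5


def select_rasirna_candidates(
    annotated: Sequence[AnnotatedRead],
    length_window: tuple[int, int] = LENGTH_WINDOW,
    max_loci: int = MAX_LOCI,
) -> list[AnnotatedRead]:
    """Retain unannotated reads in the length window with 1..max_loci hits."""
    lo, hi = length_window
    return [
        ar
        for ar in annotated
        if ar.category == "unannotated"
        and lo <= len(ar.sequence) <= hi
        and 1 <= ar.n_loci <= max_loci
    ]


def fivep_bias(candidates: Sequence[AnnotatedRead]) -> tuple[pd.DataFrame, float | None]:
    """Positional base frequencies (RNA letters) over unique reads, unweighted.

    Returns the position x {A, C, G, U} matrix (rows sum to 1 over reads
    long enough to cover the position) and the first-base U fraction,
    or ``None`` for an empty candidate set.
    """
    if not candidates:
        return pd.DataFrame(columns=["A", "C", "G", "U"]), None
    max_len = max(len(ar.sequence) for ar in candidates)
    counts = np.zeros((max_len, 4), dtype=float)
    col = {"A": 0, "C": 1, "G": 2, "T": 3}
    for ar in candidates:
        for i, base in enumerate(ar.sequence):
            counts[i, col[base]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    df = pd.DataFrame(freqs, columns=["A", "C", "G", "U"])
    df.index = pd.RangeIndex(1, max_len + 1, name="position")
    return df, float(df.iloc[0]["U"])


def chrom_distribution(
    candidates: Sequence[AnnotatedRead],
    genome: dict[str, str],
    tracks: Iterable[Interval] = (),
) -> pd.DataFrame:
    """Per-chromosome candidate load, normalized to chromosome length.

    Multi-locus reads contribute 1/n_loci per hit.  Reported both ways
    (unique-read weighted and copy weighted), together with the fraction
    of chromosome bases covered by exons and by repeats.
    """
    uniq = {c: 0.0 for c in genome}
    copies = {c: 0.0 for c in genome}
    for ar in candidates:
        w = 1.0 / ar.n_loci
        for hit in ar.hits:
            if hit.chrom not in genome:
                raise KeyError(f"hit chromosome {hit.chrom!r} absent from genome")
            uniq[hit.chrom] += w
            copies[hit.chrom] += w * ar.unique_read.total

    exon_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    repeat_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    for iv in tracks:
        if iv.category == "exon" and iv.chrom in exon_spans:
            exon_spans[iv.chrom].append((iv.start, iv.end))
        elif iv.category.startswith("repeat:") or iv.category in (
            "LINE",
            "LTR",
            "satellite",
            "other_repeat",
        ):
            if iv.chrom in repeat_spans:
                repeat_spans[iv.chrom].append((iv.start, iv.end))

    rows = []
    for chrom, seq in genome.items():
        n = len(seq)
        mb = n / 1e6
        exon_bases = sum(e - s for s, e in merge_spans(exon_spans[chrom]))
        repeat_bases = sum(e - s for s, e in merge_spans(repeat_spans[chrom]))
        rows.append(
            {
                "chrom": chrom,
                "length": n,
                "n_unique": uniq[chrom],
                "n_copies": copies[chrom],
                "density_unique_per_mb": uniq[chrom] / mb,
                "density_copies_per_mb": copies[chrom] / mb,
                "exon_base_fraction": exon_bases / n,
                "repeat_base_fraction": repeat_bases / n,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DensityTrack:
    """Windowed values along one chromosome (window anchored at 0)."""

    chrom: str
    window_size: int
    step: int
    starts: np.ndarray
    values: np.ndarray
    strand: str  # '+', '-', or 'both'
    feature: str  # 'exon' | 'repeat' | 'reads' | track category
    partial: np.ndarray | None = None  # True where the window is truncated


def _window_starts(chrom_len: int, step: int) -> np.ndarray:
    return np.arange(0, max(chrom_len, 1), step, dtype=np.int64)


def feature_density(
    track: Iterable[Interval],
    chrom: str,
    chrom_len: int,
    window_size: int = 50_000,
    step: int = 1_000,
    feature: str = "feature",
) -> DensityTrack:
    """Fraction of each window's bases covered by the feature.

    Overlapping intervals are merged first, so the value is invariant to
    splitting a feature into adjacent pieces.  Windows tile from 0 every
    ``step``; windows running past the chromosome end are truncated and
    flagged, and the fraction is taken over the truncated width.
    """
    if not (window_size >= step > 0):
        raise ValueError("require window_size >= step > 0")
    merged = merge_spans([(iv.start, iv.end) for iv in track if iv.chrom == chrom])
    starts = _window_starts(chrom_len, step)
    values = np.zeros(len(starts))
    partial = np.zeros(len(starts), dtype=bool)
    for i, s in enumerate(starts):
        e = min(s + window_size, chrom_len)
        width = e - s
        partial[i] = width < window_size
        values[i] = covered_bases(merged, int(s), int(e)) / width if width else 0.0
    return DensityTrack(chrom, window_size, step, starts, values, "both", feature, partial)


def read_density(
    candidates: Sequence[AnnotatedRead],
    chrom: str,
    chrom_len: int,
    strand: str,
    window_size: int = 5_000,
    step: int = 100,
    weight: str = "unique",
    max_loci: int = MAX_LOCI,
) -> DensityTrack:
    """Windowed candidate 5'-end count (weighted 1/n_loci) for one strand."""
    if strand not in "+-":
        raise ValueError(f"invalid strand {strand!r}")
    if not (window_size >= step > 0):
        raise ValueError("require window_size >= step > 0")
    if weight not in ("unique", "copies"):
        raise ValueError(f"invalid weight {weight!r}")
    positions: list[int] = []
    weights: list[float] = []
    for ar in candidates:
        assert 1 <= ar.n_loci <= max_loci, "candidate filter must run upstream"
        w = 1.0 / ar.n_loci
        if weight == "copies":
            w *= ar.unique_read.total
        for hit in ar.hits:
            if hit.chrom == chrom and hit.strand == strand:
                positions.append(hit.five_prime())
                weights.append(w)
    pos = np.asarray(positions, dtype=np.int64)
    wts = np.asarray(weights, dtype=float)
    order = np.argsort(pos, kind="stable")
    pos, wts = pos[order], wts[order]
    cum = np.concatenate([[0.0], np.cumsum(wts)])
    starts = _window_starts(chrom_len, step)
    ends = np.minimum(starts + window_size, chrom_len)
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, ends, side="left")
    values = cum[hi] - cum[lo]
    partial = (starts + window_size) > chrom_len
    return DensityTrack(chrom, window_size, step, starts, values, strand, "reads", partial)


def write_bedgraph(track: DensityTrack, path: str, chrom_len: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"track type=bedGraph name={track.feature}_{track.strand} "
            f"description=\"window={track.window_size} step={track.step}\"\n"
        )
        for s, v in zip(track.starts, track.values):
            e = s + track.step
            if chrom_len is not None:
                e = min(e, chrom_len)
            fh.write(f"{track.chrom}\t{s}\t{e}\t{v:.6g}\n")
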