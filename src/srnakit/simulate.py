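"""Synthetic small-RNA worlds: toy genome, annotation tracks, and libraries.

The generator produces a random genome, plants annotation intervals on it
(ncRNA classes, miRNA hairpins with matures, repeat families stamped as
identical copies, exons), and then draws sequencing libraries whose reads
are genuine genome substrings.  Every emitted read carries a ground-truth
row (source category, source interval, strand, intended length,
contamination flag), so downstream modules can be validated against the
simulation rather than against each other.

Three library archetypes ship as a versioned config
(``srnakit/data/archetypes.yaml``): an ovary-like library dominated by a
22 nt miRNA mode, a testis-like library with 24/27 nt modes, a planted
repeat share of 0.36 and a 5'-U bias on repeat- and intergenic-derived
reads, and an IP-like library with a 24-25 nt peak and a depleted miRNA
fraction.
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from pyfaidx import Faidx

from ._intervals import Interval, merge_spans, write_bed, write_gff3
from ._io import FastqRead, revcomp, write_fasta, write_fastq

__all__ = [
    "CATEGORIES",
    "GenomeSpec",
    "AnnotationSpec",
    "Annotations",
    "LibraryArchetype",
    "make_genome",
    "write_genome",
    "make_annotations",
    "simulate_library",
    "default_annotation_spec",
    "default_genome_spec",
    "load_archetype",
    "default_adapter",
]

#: Fixed annotation vocabulary for generated tracks.
CATEGORIES = (
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "miRNA_hairpin",
    "LINE",
    "LTR",
    "satellite",
    "other_repeat",
    "exon",
)

_REPEAT_CATEGORIES = ("LINE", "LTR", "satellite", "other_repeat")
#: Source categories a library may draw reads from: the annotation
#: vocabulary plus "intergenic" (reads from unannotated gaps).
_SOURCE_CATEGORIES = CATEGORIES + ("intergenic",)

_GOOD_Q = "I"  # Phred 40
_BAD_Q = "#"  # Phred 2


# ---------------------------------------------------------------------------
# genome


@dataclass(frozen=True)
class GenomeSpec:
    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    gc_fraction: float = 0.42
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        for name, n in zip(self.chrom_names, self.chrom_lengths):
            if n <= 0:
                raise ValueError(f"chromosome {name}: non-positive length {n}")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(f"gc_fraction {self.gc_fraction} outside [0, 1]")


def default_genome_spec(seed: int = 0) -> GenomeSpec:
    return GenomeSpec(
        chrom_names=("chr1", "chr2", "chr3", "chrZ", "chrW"),
        chrom_lengths=(240_000, 180_000, 120_000, 80_000, 60_000),
        gc_fraction=0.42,
        seed=seed,
    )


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def make_genome(spec: GenomeSpec) -> dict[str, str]:
    """Generate a random genome as ``{chrom: sequence}``, deterministic in seed."""
    rng = np.random.default_rng(spec.seed)
    return {
        name: _random_seq(rng, n, spec.gc_fraction)
        for name, n in zip(spec.chrom_names, spec.chrom_lengths)
    }


def write_genome(genome: dict[str, str], path: str) -> None:
    """Write the genome FASTA and build a .fai index next to it."""
    write_fasta(genome, path)
    Faidx(path)


# ---------------------------------------------------------------------------
# annotations


@dataclass(frozen=True)
class AnnotationSpec:
    """How many intervals of each category to plant, and how long.

    ``family_copies`` gives the number of identical genomic copies per
    repeat family; copies share one stamped consensus sequence, which is
    what makes repeat-derived reads genuinely multimapping.
    """

    counts: dict[str, int]
    length_ranges: dict[str, tuple[int, int]]
    family_copies: dict[str, int] = field(
        default_factory=lambda: {"LINE": 3, "LTR": 2, "satellite": 6, "other_repeat": 1}
    )
    chrom_weights: dict[str, dict[str, float]] = field(default_factory=dict)
    mature_length_probs: dict[int, float] = field(
        default_factory=lambda: {21: 0.25, 22: 0.5, 23: 0.25}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for cat in self.counts:
            if cat not in CATEGORIES:
                raise ValueError(f"unknown annotation category {cat!r}")


def default_annotation_spec(seed: int = 0) -> AnnotationSpec:
    return AnnotationSpec(
        counts={
            "rRNA": 8,
            "tRNA": 20,
            "snRNA": 10,
            "snoRNA": 10,
            "miRNA_hairpin": 40,
            "LINE": 24,
            "LTR": 18,
            "satellite": 12,
            "other_repeat": 10,
            "exon": 60,
        },
        length_ranges={
            "rRNA": (120, 1800),
            "tRNA": (70, 90),
            "snRNA": (100, 300),
            "snoRNA": (60, 200),
            "miRNA_hairpin": (70, 90),
            "LINE": (400, 2000),
            "LTR": (300, 1000),
            "satellite": (150, 500),
            "other_repeat": (100, 500),
            "exon": (100, 300),
        },
        chrom_weights={
            cat: {"chr1": 0.1, "chr2": 0.1, "chr3": 0.1, "chrZ": 0.2, "chrW": 0.5}
            for cat in _REPEAT_CATEGORIES
        },
        seed=seed,
    )


@dataclass
class Annotations:
    """Generated annotation bundle.

    ``genome`` is the (possibly repeat-stamped) genome the tracks refer
    to; downstream stages must map against this copy, not the pre-stamp
    genome.
    """

    intervals: list[Interval]
    mature_intervals: list[Interval]
    hairpin_seqs: dict[str, str]
    mature_seqs: dict[str, str]
    gaps: dict[str, list[tuple[int, int]]]
    genome: dict[str, str]

    def write(self, outdir: str) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        write_bed(self.intervals + self.mature_intervals, os.path.join(outdir, "tracks.bed"))
        write_gff3(self.intervals + self.mature_intervals, os.path.join(outdir, "tracks.gff3"))
        write_fasta(self.hairpin_seqs, os.path.join(outdir, "hairpins.fa"))
        write_fasta(self.mature_seqs, os.path.join(outdir, "matures.fa"))


def _pick_chrom(rng, genome, weights: dict[str, float] | None) -> str:
    names = list(genome)
    if weights:
        w = np.array([weights.get(c, 0.0) for c in names], dtype=float)
    else:
        w = np.array([len(genome[c]) for c in names], dtype=float)
    return names[rng.choice(len(names), p=w / w.sum())]

def _place(rng, genome, occupied, length, weights, max_tries=2000) -> tuple[str, int]:
    """Find a non-overlapping slot of `length`; rejection sampling."""
    if length > max(len(s) for s in genome.values()):
        raise ValueError(f"requested interval of length {length} exceeds every chromosome")
    for _ in range(max_tries):
        chrom = _pick_chrom(rng, genome, weights)
        if length > len(genome[chrom]):
            continue
        start = int(rng.integers(0, len(genome[chrom]) - length + 1))
        spans = occupied.setdefault(chrom, [])
        if all(e <= start or s >= start + length for s, e in spans):
            spans.append((start, start + length))
            return chrom, start
    raise RuntimeError(f"could not place interval of length {length}; genome too crowded")


def make_annotations(
    genome: dict[str, str], spec: AnnotationSpec
) -> Annotations:
    """Plant annotation intervals on a genome.

    Repeat families are stamped into the genome sequence (identical
    copies), so the returned :class:`Annotations` carries the updated
    genome.  Mature miRNAs are exact subsequences of their hairpins.
    """
    rng = np.random.default_rng(spec.seed)
    genome = dict(genome)  # shallow copy; chromosomes replaced on stamping
    occupied: dict[str, list[tuple[int, int]]] = {}
    intervals: list[Interval] = []
    mature_intervals: list[Interval] = []
    hairpin_seqs: dict[str, str] = {}
    mature_seqs: dict[str, str] = {}

    for cat in CATEGORIES:
        n = spec.counts.get(cat, 0)
        if n == 0:
            continue
        lo, hi = spec.length_ranges[cat]
        weights = spec.chrom_weights.get(cat)
        if cat in _REPEAT_CATEGORIES:
            copies = max(1, spec.family_copies.get(cat, 1))
            n_families = (n + copies - 1) // copies
            placed = 0
            for fam in range(n_families):
                length = int(rng.integers(lo, hi + 1))
                consensus = _random_seq(rng, length, 0.42)
                for c in range(copies):
                    if placed >= n:
                        break
                    chrom, start = _place(rng, genome, occupied, length, weights)
                    genome[chrom] = (
                        genome[chrom][:start] + consensus + genome[chrom][start + length:]
                    )
                    strand = "+" if rng.random() < 0.5 else "-"
                    intervals.append(
                        Interval(chrom, start, start + length, f"{cat}-f{fam}c{c}", strand, cat)
                    )
                    placed += 1
        elif cat == "miRNA_hairpin":
            m_lens = sorted(spec.mature_length_probs)
            m_p = np.array([spec.mature_length_probs[k] for k in m_lens], dtype=float)
            m_p = m_p / m_p.sum()
            for i in range(n):
                hlen = int(rng.integers(lo, hi + 1))
                chrom, start = _place(rng, genome, occupied, hlen, weights)
                strand = "+" if rng.random() < 0.5 else "-"
                hp_id = f"sim-mir-{i + 1}"
                mat_id = f"sim-miR-{i + 1}"
                intervals.append(Interval(chrom, start, start + hlen, hp_id, strand, cat))
                hseq = genome[chrom][start : start + hlen]
                if strand == "-":
                    hseq = revcomp(hseq)
                mlen = int(m_lens[rng.choice(len(m_lens), p=m_p)])
                # mature sits on the 5' arm, a few nt in from the hairpin end
                off = int(rng.integers(3, 12))
                if strand == "+":
                    ms = start + off
                else:
                    ms = start + hlen - off - mlen
                mature_intervals.append(
                    Interval(chrom, ms, ms + mlen, mat_id, strand, "miRNA_mature")
                )
                hairpin_seqs[hp_id] = hseq
                mature_seqs[mat_id] = hseq[off : off + mlen]
        else:
            for i in range(n):
                length = int(rng.integers(lo, hi + 1))
                chrom, start = _place(rng, genome, occupied, length, weights)
                strand = "+" if rng.random() < 0.5 else "-"
                intervals.append(
                    Interval(chrom, start, start + length, f"{cat}-{i + 1}", strand, cat)
                )

    gaps: dict[str, list[tuple[int, int]]] = {}
    min_gap = 80
    for chrom, seq in genome.items():
        merged = merge_spans(occupied.get(chrom, []))
        prev = 0
        out: list[tuple[int, int]] = []
        for s, e in merged + [(len(seq), len(seq))]:
            if s - prev >= min_gap:
                out.append((prev, s))
            prev = max(prev, e)
        gaps[chrom] = out

    return Annotations(intervals, mature_intervals, hairpin_seqs, mature_seqs, gaps, genome)


# ---------------------------------------------------------------------------
# library archetypes


def default_adapter() -> str:
    return str(_load_config()["adapter"])


@dataclass(frozen=True)
class LibraryArchetype:
    name: str
    length_mixture: dict[int, float]
    category_mixture: dict[str, float]
    fivep_u_bias: float
    isomir_shift_probs: dict[int, float]
    adapter_dimer_rate: float
    low_quality_rate: float
    n_reads: int = 50_000
    seed: int = 0
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    intergenic_chrom_weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for label, mix in (
            ("length_mixture", self.length_mixture),
            ("category_mixture", self.category_mixture),
            ("isomir_shift_probs", self.isomir_shift_probs),
        ):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{label} sums to {total}, expected 1")
        for label, rate in (
            ("fivep_u_bias", self.fivep_u_bias),
            ("adapter_dimer_rate", self.adapter_dimer_rate),
            ("low_quality_rate", self.low_quality_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{label} {rate} outside [0, 1]")
        for cat in self.category_mixture:
            if cat not in _SOURCE_CATEGORIES:
                raise ValueError(f"unknown source category {cat!r}")


def _load_config() -> dict:
    ref = importlib.resources.files("srnakit") / "data" / "archetypes.yaml"
    with ref.open() as fh:
        return yaml.safe_load(fh)


def load_archetype(name: str, n_reads: int = 50_000, seed: int = 0, **overrides) -> LibraryArchetype:
    """Load one of the shipped archetypes (ovary_like / testis_like / ip_like)."""
    cfg = _load_config()
    if name not in cfg["archetypes"]:
        raise KeyError(f"unknown archetype {name!r}; have {sorted(cfg['archetypes'])}")
    raw = dict(cfg["archetypes"][name])
    params = dict(
        name=name,
        length_mixture={int(k): float(v) for k, v in raw["length_mixture"].items()},
        category_mixture={str(k): float(v) for k, v in raw["category_mixture"].items()},
        fivep_u_bias=float(raw["fivep_u_bias"]),
        isomir_shift_probs={int(k): float(v) for k, v in raw["isomir_shift_probs"].items()},
        adapter_dimer_rate=float(raw["adapter_dimer_rate"]),
        low_quality_rate=float(raw["low_quality_rate"]),
        n_reads=n_reads,
        seed=seed,
        adapter=str(cfg["adapter"]),
        intergenic_chrom_weights=raw.get("intergenic_chrom_weights"),
    )
    params.update(overrides)
    return LibraryArchetype(**params)


# ---------------------------------------------------------------------------
# library simulation

_TRUTH_COLUMNS = [
    "read_id",
    "category",
    "chrom",
    "start",
    "end",
    "strand",
    "length",
    "first_base_u",
    "contaminant",
]


def _read_from_span(genome, chrom, start, length, strand) -> str:
    s = genome[chrom][start : start + length]
    return revcomp(s) if strand == "-" else s


def _five_prime_base(genome, chrom, start, length, strand) -> str:
    if strand == "+":
        return genome[chrom][start]
    return revcomp(genome[chrom][start + length - 1])


def simulate_library(
    genome: dict[str, str],
    ann: Annotations,
    arch: LibraryArchetype,
) -> tuple[list[FastqRead], pd.DataFrame]:
    """Draw one library from an archetype.

    Returns the raw FASTQ reads (insert + 3' adapter, Sanger qualities)
    and a truth table with one row per emitted read.  Reads are exact
    genome substrings, so the round trip through the exact mapper
    recovers the source locus.  The 5'-U bias applies to repeat- and
    intergenic-derived reads: with probability ``fivep_u_bias`` the
    sampled locus is required to start with T on the read strand, and
    with the complementary probability it is required not to, making the
    planted first-base-U rate exactly the configured value.
    """
    if genome is not ann.genome:
        genome = ann.genome  # tracks refer to the stamped genome
    rng = np.random.default_rng(arch.seed)

    by_cat: dict[str, list[Interval]] = {}
    for iv in ann.intervals:
        by_cat.setdefault(iv.category, []).append(iv)
    for cat, w in arch.category_mixture.items():
        if w > 0 and cat != "intergenic" and not by_cat.get(cat):
            raise ValueError(f"category {cat!r} has weight {w} but no intervals")

    gap_list = [
        (chrom, s, e) for chrom, spans in ann.gaps.items() for s, e in spans if e - s >= 40
    ]
    if arch.category_mixture.get("intergenic", 0) > 0 and not gap_list:
        raise ValueError("category 'intergenic' has weight but no gaps are available")
    if arch.intergenic_chrom_weights:
        gap_w = np.array(
            [arch.intergenic_chrom_weights.get(c, 0.0) * (e - s) for c, s, e in gap_list]
        )
    else:
        gap_w = np.array([float(e - s) for c, s, e in gap_list])
    gap_p = gap_w / gap_w.sum() if len(gap_list) else None

    cats = sorted(arch.category_mixture)
    cat_p = np.array([arch.category_mixture[c] for c in cats])
    cat_p = cat_p / cat_p.sum()
    lens = sorted(arch.length_mixture)
    len_p = np.array([arch.length_mixture[k] for k in lens])
    len_p = len_p / len_p.sum()
    shifts = sorted(arch.isomir_shift_probs)
    shift_p = np.array([arch.isomir_shift_probs[k] for k in shifts])
    shift_p = shift_p / shift_p.sum()

    matures = ann.mature_intervals
    if matures:
        # mildly skewed locus expression so isomiR clusters have depth
        mat_w = 1.0 / (1.0 + np.arange(len(matures)))
        mat_p = mat_w / mat_w.sum()
    hairpin_by_mature = {}
    hp_by_name = {iv.name: iv for iv in ann.intervals if iv.category == "miRNA_hairpin"}
    for m in matures:
        hp_id = m.name.replace("miR", "mir")
        hairpin_by_mature[m.name] = hp_by_name[hp_id]

    u_draw = rng.random(arch.n_reads)
    contam_draw = rng.random(arch.n_reads)
    cat_idx = rng.choice(len(cats), size=arch.n_reads, p=cat_p)
    len_idx = rng.choice(len(lens), size=arch.n_reads, p=len_p)

    reads: list[FastqRead] = []
    truth_rows: list[tuple] = []
    for i in range(arch.n_reads):
        rid = f"r{i:06d}"
        if contam_draw[i] < arch.adapter_dimer_rate:
            seq = arch.adapter
            reads.append(FastqRead(rid, seq, _GOOD_Q * len(seq)))
            truth_rows.append((rid, "", "", -1, -1, ".", 0, False, "adapter_dimer"))
            continue
        low_q = contam_draw[i] < arch.adapter_dimer_rate + arch.low_quality_rate

        cat = cats[cat_idx[i]]
        if cat == "miRNA_hairpin":
            m = matures[rng.choice(len(matures), p=mat_p)]
            hp = hairpin_by_mature[m.name]
            d5 = int(shifts[rng.choice(len(shifts), p=shift_p)])
            d3 = int(shifts[rng.choice(len(shifts), p=shift_p)])
            if m.strand == "+":
                s, e = m.start - d5, m.end + d3
            else:
                s, e = m.start - d3, m.end + d5
            s, e = max(s, hp.start), min(e, hp.end)
            chrom, strand = m.chrom, m.strand
            L = e - s
        elif cat == "intergenic":
            L = int(lens[len_idx[i]])
            want_u = u_draw[i] < arch.fivep_u_bias
            chrom = s = strand = None
            for _ in range(300):
                gi = int(rng.choice(len(gap_list), p=gap_p))
                gc_, gs, ge = gap_list[gi]
                if ge - gs < L:
                    continue
                cand_s = int(rng.integers(gs, ge - L + 1))
                cand_strand = "+" if rng.random() < 0.5 else "-"
                base = _five_prime_base(genome, gc_, cand_s, L, cand_strand)
                if (base == "T") == want_u:
                    chrom, s, strand = gc_, cand_s, cand_strand
                    break
            if chrom is None:
                chrom, s, strand = gc_, cand_s, cand_strand
            e = s + L
        else:
            ivs = by_cat[cat]
            L = int(lens[len_idx[i]])
            is_repeat = cat in _REPEAT_CATEGORIES
            want_u = is_repeat and (u_draw[i] < arch.fivep_u_bias)
            want_not_u = is_repeat and not want_u
            chrom = s = strand = None
            for _ in range(300):
                iv = ivs[int(rng.integers(len(ivs)))]
                Lc = min(L, iv.length)
                cand_s = int(rng.integers(iv.start, iv.end - Lc + 1))
                if is_repeat:
                    cand_strand = "+" if rng.random() < 0.5 else "-"
                else:
                    cand_strand = iv.strand
                base = _five_prime_base(genome, iv.chrom, cand_s, Lc, cand_strand)
                if not is_repeat or (base == "T") == want_u:
                    chrom, s, strand, L = iv.chrom, cand_s, cand_strand, Lc
                    break
            if chrom is None:
                chrom, s, strand, L = iv.chrom, cand_s, cand_strand, Lc
            e = s + L

        insert = _read_from_span(genome, chrom, s, L, strand)
        seq = insert + arch.adapter
        qual = (_BAD_Q if low_q else _GOOD_Q) * len(seq)
        reads.append(FastqRead(rid, seq, qual))
        truth_rows.append(
            (
                rid,
                cat,
                chrom,
                s,
                e,
                strand,
                L,
                insert[:1] == "T",
                "low_quality" if low_q else "",
            )
        )

    truth = pd.DataFrame(truth_rows, columns=_TRUTH_COLUMNS)
    return reads, truth


def write_library(reads: Iterable[FastqRead], truth: pd.DataFrame, fastq_path: str, truth_path: str) -> None:
    write_fastq(reads, fastq_path)
    truth.to_csv(truth_path, sep="\t", index=False)
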