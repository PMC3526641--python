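"""End-to-end orchestration: simulate (or load) libraries, clean,
collapse, map/annotate, profile miRNAs and rasiRNA candidates, and write
the paper-shaped TSV/bedGraph bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
import yaml

from . import annotate as _annotate
from . import mirna as _mirna
from . import preprocess as _pre
from . import rasirna as _ras
from . import simulate as _sim
from .annotate import AnnotationTracks, GenomeIndex
from .preprocess import MAIN_WINDOW

log = logging.getLogger("srnakit")

__all__ = ["PipelineConfig", "run_all", "length_histogram"]


@dataclass
class PipelineConfig:
    """Validated, serializable run configuration."""

    out_dir: str
    seed: int = 0
    n_reads: int = 20_000
    archetypes: tuple[str, ...] = ("testis_like", "ovary_like", "ip_like")
    min_len: int = MAIN_WINDOW[0]
    max_len: int = MAIN_WINDOW[1]
    quality_floor: float = 20.0
    rasirna_window: tuple[int, int] = _ras.LENGTH_WINDOW
    max_loci: int = _ras.MAX_LOCI
    de_alpha: float = 0.05
    de_pair: tuple[str, str] = ("testis_like", "ovary_like")
    feature_window: int = 50_000
    feature_step: int = 1_000
    read_window: int = 5_000
    read_step: int = 100
    priority: tuple[str, ...] = _annotate.DEFAULT_PRIORITY
    rasirna_library: str = "testis_like"
    write_plots: bool = False

    def validate(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        if not (self.feature_window >= self.feature_step > 0):
            raise ValueError("feature window/step invalid")
        if not (self.read_window >= self.read_step > 0):
            raise ValueError("read window/step invalid")
        for lib in self.de_pair:
            if lib not in self.archetypes:
                raise ValueError(f"de_pair library {lib!r} not among archetypes")
        if self.rasirna_library not in self.archetypes:
            raise ValueError(f"rasirna_library {self.rasirna_library!r} not among archetypes")

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for f in dataclasses.fields(cls):
            if f.name in d and isinstance(d[f.name], list):
                d[f.name] = tuple(d[f.name])
        return cls(**d)


def length_histogram(
    reads: Sequence, weight: str = "copies", lo: int = 18, hi: int = 32
) -> pd.DataFrame:
    """Per-length table over [lo, hi].

    ``reads`` may be clean sequences (strings) or UniqueRead objects;
    ``weight`` selects unique-family counting or copy-number counting.
    """
    if weight not in ("unique", "copies"):
        raise ValueError(f"invalid weight {weight!r}")
    counts = {n: 0 for n in range(lo, hi + 1)}
    for r in reads:
        if isinstance(r, str):
            n, w = len(r), 1
        else:
            n, w = len(r.sequence), (1 if weight == "unique" else r.total)
        if n in counts:
            counts[n] += w
    return pd.DataFrame({"length": list(counts), "count": list(counts.values())})


def run_all(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns the in-memory bundle, writes TSVs.

    Raises at the failing stage with its name; count conservation is
    asserted after every cleaning and annotation stage.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    config.to_yaml(os.path.join(config.out_dir, "config.yaml"))

    log.info("stage simulate: genome + annotations, seed=%d", config.seed)
    genome = _sim.make_genome(_sim.default_genome_spec(seed=config.seed))
    ann = _sim.make_annotations(genome, _sim.default_annotation_spec(seed=config.seed + 1))
    genome = ann.genome
    _sim.write_genome(genome, os.path.join(config.out_dir, "genome.fa"))
    ann.write(config.out_dir)

    tracks = AnnotationTracks(ann.intervals, priority=config.priority)
    index = GenomeIndex(genome)

    bundle: dict = {"genome": genome, "annotations": ann, "libraries": {}}
    clean_totals: dict[str, int] = {}
    per_lib_uniques = {}
    for k, name in enumerate(config.archetypes):
        arch = _sim.load_archetype(name, n_reads=config.n_reads, seed=config.seed + 10 + k)
        reads, truth = _sim.simulate_library(genome, ann, arch)
        truth.to_csv(os.path.join(config.out_dir, f"{name}.truth.tsv"), sep="\t", index=False)
        _sim.write_fastq(reads, os.path.join(config.out_dir, f"{name}.fastq"))

        clean, report = _pre.clean_reads(
            reads, arch.adapter, config.min_len, config.max_len, config.quality_floor
        )
        report.check_balance()
        log.info("stage clean[%s]: raw=%d clean=%d", name, report.n_raw, report.n_clean)
        with open(os.path.join(config.out_dir, f"{name}.cleaning.json"), "w") as fh:
            fh.write(report.to_json())

        uniques = _pre.collapse_unique(clean, name)
        if sum(u.total for u in uniques) != report.n_clean:
            raise AssertionError(f"stage collapse[{name}]: count conservation violated")
        per_lib_uniques[name] = uniques
        clean_totals[name] = report.n_clean

        annotated = _annotate.annotate_all(uniques, index, tracks)
        n_copies = sum(a.unique_read.total for a in annotated)
        if n_copies != report.n_clean:
            raise AssertionError(f"stage annotate[{name}]: copies != n_clean")
        table = _annotate.category_table(annotated)
        table.to_csv(
            os.path.join(config.out_dir, f"{name}.categories.tsv"), sep="\t", index=False
        )
        for w in ("unique", "copies"):
            hist = length_histogram(annotated, weight=w)
            hist.to_csv(
                os.path.join(config.out_dir, f"{name}.lengths.{w}.tsv"), sep="\t", index=False
            )
        bundle["libraries"][name] = {
            "report": report,
            "uniques": uniques,
            "annotated": annotated,
            "category_table": table,
        }

    # miRNA catalog over the merged collection (per-library counts retained)
    merged = _pre.merge_libraries(per_lib_uniques.values())
    annotated_merged = _annotate.annotate_all(merged, index, tracks)
    clusters = _mirna.cluster_isomiRs(annotated_merged, ann.mature_intervals)
    labels = {
        name: _mirna.classify_seven_groups(
            bundle["libraries"][name]["annotated"],
            ann.mature_seqs,
            ann.hairpin_seqs,
            ann.mature_intervals,
            [iv for iv in ann.intervals if iv.category == "miRNA_hairpin"],
        )
        for name in config.archetypes
    }
    gtable = _mirna.group_table(labels)
    gtable.to_csv(os.path.join(config.out_dir, "mirna_groups.tsv"), sep="\t", index=False)

    lib_a, lib_b = config.de_pair
    de = _mirna.differential_from_clusters(
        clusters,
        lib_a,
        lib_b,
        clean_totals[lib_a],
        clean_totals[lib_b],
        alpha=config.de_alpha,
    )
    de.to_csv(os.path.join(config.out_dir, "mirna_de.tsv"), sep="\t", index=False)
    bundle["clusters"] = clusters
    bundle["de_table"] = de
    bundle["group_table"] = gtable

    # rasiRNA characterization on the configured library
    ras_lib = config.rasirna_library
    candidates = _ras.select_rasirna_candidates(
        bundle["libraries"][ras_lib]["annotated"],
        length_window=config.rasirna_window,
        max_loci=config.max_loci,
    )
    matrix, u_frac = _ras.fivep_bias(candidates)
    matrix.to_csv(os.path.join(config.out_dir, "rasirna_base_bias.tsv"), sep="\t")
    chrom_table = _ras.chrom_distribution(candidates, genome, ann.intervals)
    chrom_table.to_csv(
        os.path.join(config.out_dir, "rasirna_chrom_distribution.tsv"), sep="\t", index=False
    )
    repeat_ivs = [
        iv
        for iv in ann.intervals
        if iv.category in ("LINE", "LTR", "satellite", "other_repeat")
    ]
    exon_ivs = [iv for iv in ann.intervals if iv.category == "exon"]
    for chrom in genome:
        n = len(genome[chrom])
        for nm, ivs in (("exon", exon_ivs), ("repeat", repeat_ivs)):
            tr = _ras.feature_density(
                ivs, chrom, n, config.feature_window, config.feature_step, feature=nm
            )
            _ras.write_bedgraph(
                tr, os.path.join(config.out_dir, f"{chrom}.{nm}.density.bedgraph"), n
            )
        for strand, tag in (("+", "plus"), ("-", "minus")):
            tr = _ras.read_density(
                candidates, chrom, n, strand, config.read_window, config.read_step,
                max_loci=config.max_loci,
            )
            _ras.write_bedgraph(
                tr, os.path.join(config.out_dir, f"{chrom}.reads.{tag}.bedgraph"), n
            )
    bundle["candidates"] = candidates
    bundle["fivep_u_fraction"] = u_frac
    bundle["chrom_distribution"] = chrom_table

    with open(os.path.join(config.out_dir, "run_summary.json"), "w") as fh:
        json.dump(
            {
                "clean_totals": clean_totals,
                "n_candidates": len(candidates),
                "fivep_u_fraction": u_frac,
                "n_clusters": len(clusters),
            },
            fh,
            indent=2,
        )
    return bundle
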