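"""Shared fixtures: a small synthetic world reused across test modules."""

import pytest

from srnakit import annotate as ann
from srnakit import preprocess as pre
from srnakit import simulate as sim


def small_genome_spec(seed: int = 11) -> sim.GenomeSpec:
    return sim.GenomeSpec(
        chrom_names=("chr1", "chr2", "chrW"),
        chrom_lengths=(60_000, 40_000, 20_000),
        gc_fraction=0.42,
        seed=seed,
    )


def small_annotation_spec(seed: int = 12) -> sim.AnnotationSpec:
    return sim.AnnotationSpec(
        counts={
            "rRNA": 4,
            "tRNA": 8,
            "snRNA": 4,
            "snoRNA": 4,
            "miRNA_hairpin": 15,
            "LINE": 9,
            "LTR": 6,
            "satellite": 6,
            "other_repeat": 4,
            "exon": 20,
        },
        length_ranges={
            "rRNA": (120, 800),
            "tRNA": (70, 90),
            "snRNA": (100, 200),
            "snoRNA": (60, 150),
            "miRNA_hairpin": (70, 90),
            "LINE": (300, 900),
            "LTR": (250, 600),
            "satellite": (150, 400),
            "other_repeat": (100, 300),
            "exon": (100, 250),
        },
        chrom_weights={
            cat: {"chr1": 0.15, "chr2": 0.15, "chrW": 0.7}
            for cat in ("LINE", "LTR", "satellite", "other_repeat")
        },
        seed=seed,
    )


@pytest.fixture(scope="session")
def world():
    genome = sim.make_genome(small_genome_spec())
    annotations = sim.make_annotations(genome, small_annotation_spec())
    return annotations


@pytest.fixture(scope="session")
def genome_index(world):
    return ann.GenomeIndex(world.genome)


@pytest.fixture(scope="session")
def tracks(world):
    return ann.AnnotationTracks(world.intervals)


@pytest.fixture(scope="session")
def testis_sim(world):
    arch = sim.load_archetype("testis_like", n_reads=6_000, seed=21)
    reads, truth = sim.simulate_library(world.genome, world, arch)
    return arch, reads, truth


@pytest.fixture(scope="session")
def testis_annotated(world, genome_index, tracks, testis_sim):
    arch, reads, truth = testis_sim
    clean, report = pre.clean_reads(reads, arch.adapter)
    uniques = pre.collapse_unique(clean, "testis_like")
    annotated = ann.annotate_all(uniques, genome_index, tracks)
    return report, uniques, annotated
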