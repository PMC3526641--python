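# srnakit

A small-RNA library characterization toolkit. It reimplements, as a
tested and reusable pipeline, the desk analysis around a germline
small-RNA sequencing study:

- **`srnakit.simulate`** — synthetic genome, annotation tracks (ncRNA
  classes, miRNA hairpins with matures, repeat families stamped as
  identical genomic copies, exons), and three library archetypes
  (`ovary_like` with a 22 nt miRNA mode; `testis_like` with 24/27 nt
  modes, a 0.36 repeat share, and a 5′-U bias on repeat/intergenic
  reads; `ip_like` with a 24–25 nt peak and a depleted miRNA fraction).
  Every simulated read carries a ground-truth row.
- **`srnakit.preprocess`** — adapter trimming (≥8 nt exact prefix
  match), contaminant/quality/length filtering with a balancing
  cleaning report, and collapsing identical reads into unique families.
- **`srnakit.annotate`** — exact (0-mismatch) multimapping on both
  strands reporting all loci, and a priority annotation cascade
  (rRNA > tRNA > snRNA > snoRNA > miRNA > repeat classes > exon >
  intron > unannotated; ncRNA/miRNA overlap is same-strand, repeat and
  exon overlap is strand-agnostic).
- **`srnakit.mirna`** — isomiR clustering per mature locus (reference =
  most abundant member, ties lexicographic), a seven-group confidence
  classification, CPM normalization, and an exact Poisson-derived
  tag-count test (the IDEG6-style statistic) with Benjamini–Hochberg
  FDR; Fisher's exact test is a configurable alternative.
- **`srnakit.rasirna`** — candidate selection (unannotated, 23–32 nt,
  1–5 loci), positional base composition and first-base-U fraction,
  chromosome-length-normalized distributions, and strand-resolved
  sliding-window densities (features: 50 kb / 1 kb; reads: 5 kb /
  100 b; multi-locus reads weighted 1/n_loci by their 5′ ends).
- **`srnakit.phyloprot`** — longest-ORF finding and translation,
  protein molecular weight (average masses) and isoelectric point
  (bisection on a Henderson–Hasselbalch charge function, EMBOSS or
  Bjellqvist pKa tables), p-distances, and UPGMA trees with Newick
  output.
- **`srnakit.pipeline` / `srnakit.cli`** — end-to-end orchestration
  producing length histograms, category tables, the seven-group table,
  the DE table, and bedGraph density tracks, deterministic under a
  fixed seed.

All genome coordinates are 0-based, half-open (BED convention).

## CLI

```sh
srnakit simulate --archetype testis_like --n-reads 50000 --seed 1 --out-dir sim/
srnakit clean sim/testis_like.fastq --out clean.fa --report cleaning.json
srnakit collapse clean.fa --library testis --out unique.fa
srnakit map-annotate unique.fa --genome sim/genome.fa --tracks sim/tracks.bed --out annotated.tsv
srnakit rasirna annotated.tsv --genome sim/genome.fa --tracks sim/tracks.bed --out-dir ras/
srnakit orf transcript.fa
srnakit protein-stats proteins.fa
srnakit upgma distances.tsv
srnakit run --out-dir out/ --seed 1 --n-reads 20000   # full pipeline
```

Exit codes: 0 success, 2 validation failure, 3 stage failure.

## Layout

```
src/srnakit/        package modules (see above)
src/srnakit/data/   versioned archetype parameter config
tests/              pytest suite (unit, property, acceptance)
scripts/            acceptance report generator
```
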