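# trlandscape

Genome-wide characterization of **large tandem repeats (TRs)** — repeat
tracts longer than the sequencing read length — from cohort matrices of
**anchored in-repeat-read (IRR) counts**, the per-locus evidence emitted by
genome-wide repeat detectors such as ExpansionHunter Denovo.

The package is for groups who hold such a locus × sample count matrix for a
control cohort and want the standard landscape analyses around it:

- **presence calling and frequency classes** — a locus is present in a
  genome when its depth-normalized count reaches 5 anchored IRRs
  (≈ 175 bp of repeat under the calibrated length model); loci in < 1% of
  genomes are *rare*, the rest *common*;
- **per-genome burdens and occurrence spectra** (how many large TRs a
  typical genome carries, how often each locus recurs in the cohort);
- **discovery saturation curves** — 1000 random genome orderings; the mean
  tail slope is the residual rate of novel loci per additional genome;
- **genomic-region and Alu-element enrichment** via a genomic-space-adjusted
  Fisher's exact test in the `bedtools fisher` construction, with the
  odds ratio OR = (n11·n22)/(n12·n21) and an explicit *undefined* state for
  degenerate tables;
- **motif composition profiling** on canonical motifs (the smallest string
  over all cyclic rotations of the unit and of its reverse complement, so
  GGGGCC ≡ CCCCGG);
- **reference-origin matching** — does a large TR overlap a reference
  simple repeat with an equivalent unit?
- **screening of known repeat-expansion disease loci** (FRDA, C9orf72/ALS,
  Fragile X, FECD, HD, CANVAS, DM2, SCA31, SCA37, ...), converting counts to
  estimated repeat numbers via the calibrated linear model
  *bases = 140.6 + 7.7 · reads*.

A first-class **synthetic-data generator** emits a complete input bundle
(genome layout, region/Alu/simple-repeat tracks, count matrix) from planted
ground truth, so every stage is testable without downloads.

## Worked example

```python
import trlandscape as tl

bundle = tl.simulate_bundle(tl.SimConfig(seed=1))          # 400 loci x 200 genomes
presence = tl.call_presence(bundle.matrix, threshold=5)
classes = tl.classify_frequency(presence, rare_fraction=0.01)
counts, summary = tl.per_genome_counts(presence, classes.classes)
```

Running `python examples/01_simulate_and_classify.py` prints:

```
cohort: 400 loci x 200 genomes
rare loci:   300  (present in < 3 genomes)
common loci: 100  (present in >= 3 genomes)

large TRs per genome (median [Q1-Q3]):
  rare    2 [1-3]
  common  25 [22-28]

39% of loci are singletons (seen in exactly one genome) - typical of a rare-dominated landscape.
```

A typical genome carries only a couple of rare large TRs but a stable
complement of common ones; about a third of loci are private to a single
genome. `examples/02_saturation.py` shows the two regimes directly: common
loci saturate after a few dozen genomes (residual rate 0.00), while rare
loci keep appearing at 0.82 novel loci per additional genome in this
synthetic cohort. The remaining examples cover enrichment, motif/origin
profiling and the disease screen; each prints its numbers with a line on
what they mean.

Real data enters through `tl.read_dense_matrix` (TSV with columns
`contig  start  end  motif  <sample>...`), `tl.read_bed_track`,
`tl.read_simple_repeats` (UCSC SimpleRepeats-style tables) and
`tl.read_disease_catalog`; `trlandscape report --config pipeline.yaml` runs
the whole pipeline from one config and writes the report tables as TSV.

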