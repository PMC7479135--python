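# Methods

## Input model

The unit of evidence is the **anchored in-repeat read (IRR)**: a read made
almost entirely of repeat motif whose mate maps uniquely near a locus.
Genome-wide detectors cluster anchored IRRs into candidate loci — each a
contig interval (0-based half-open throughout the package) with a 3–8 bp
primitive motif — and report per-sample counts. Counts are compared across
genomes after **depth normalization**, `raw × reference_depth /
sample_depth`, with a 40× reference depth (the observed mean coverage the
cohort matrices assume); when no depth metadata is supplied every sample
defaults to the reference depth, making normalization the identity.

Anchored IRR counts track the length of the larger allele approximately
linearly. The calibrated model is

    bases = 140.6 + 7.7 × reads,

an average over per-locus least-squares fits of long-range genotyper allele
sizes against IRR counts (`calibrate_model` reproduces this procedure and
reports Spearman's ρ per calibration locus). The presence threshold of
**5 normalized IRRs** corresponds to ≈ 179 bases of repeat — i.e. a call
means "repeat tract longer than a 150 bp read". The comparison is
inclusive (count ≥ 5): "a minimum of five" is taken as the operative
filter; results at a strict > 5 can be obtained by passing `threshold=5 +
ε` if a literal exclusive reading is wanted.

Because only anchored IRRs are counted, the method cannot size the two
alleles separately, saturates for very large expansions, and localizes loci
only broadly; the disease screen therefore matches catalog intervals with a
configurable ±1,000 bp slop, and flags at recessive loci are annotated as
carrier-compatible only.

## Frequency classes and saturation

A locus present in fewer than 1% of genomes is *rare*; the first common
occurrence count is `floor(rare_fraction × n) + 1`, which places the
boundary between 11 and 12 occurrences for a 1,115-genome cohort. Loci
present in no genome are reported as *absent* rather than rare, so rare +
common equals the number of loci seen at least once.

Saturation curves visit the genomes in a uniformly random order (1,000
Fisher–Yates permutations from one seed by default); a locus is *novel* at
the first visited genome carrying it, and the per-position novel counts are
averaged into a cumulative curve. The **residual discovery rate** is the
mean increment over the last 15 positions. The curve's endpoint is exactly
the number of distinct present loci for every ordering, and the tests also
check the Monte-Carlo curve against the closed-form expectation
E[cum_j] = Σ_l (1 − C(n−m_l, j)/C(n, j)) — an oracle used only for
validation, not the reported method.

## Region assignment and overlap enrichment

Region labels are assigned by priority — promoter > TTS > exon > intron >
intergenic, the precedence standard annotators use — with a ≥ 1 bp overlap
(half-open) deciding each test and intergenic as the genomic complement.
Alu overlap is likewise ≥ 1 bp intersection of the locus interval as given
(no slop by default, since the locus interval already reflects the broad
anchored-IRR localization).

Enrichment uses the `bedtools fisher` construction, verified against
bedtools 2.31.1 on toy inputs: the genome is modeled as
`floor(G / (mean_len_a + mean_len_b))` placement trials with *inclusive*
(end − start + 1) mean interval lengths; `n11` is the number of
intersecting (A, B) interval pairs; the remaining cells follow from the
margins. The reported odds ratio is the unconditional sample estimate
(n11·n22)/(n12·n21) — infinite when only the denominator vanishes — and
the two-sided p sums hypergeometric probabilities of tables no more
probable than the observed one. Dense tracks can drive a cell negative
(overlaps exceeding the interval count or the trial budget); such tables
are flagged **undefined** and no odds ratio or p is reported, rather than
clamping cells to zero and emitting a meaningless ratio.

## Motif identity and composition

A repeat unit has no intrinsic strand or phase, so motif identity is the
**canonical motif**: the lexicographically smallest string over all cyclic
rotations of the unit and of its reverse complement (GGGGCC → CCCCGG,
CAG → AGC, GAA → AAG). Units that are repetitions of a shorter unit
("ATAT") are rejected at ingestion rather than silently reduced, keeping
locus identity unambiguous. Composition tables report unique-nucleotide
counts (1–4), unordered nucleotide pairs for two-letter motifs, and unit
lengths 3–8; pairs are computed on the canonical motif by default, so
complementary reports collapse (CT-composed motifs count as A&G). The
uncollapsed mode is available (`collapse_strand=False`) since either
accounting convention is defensible.

Reference-origin matching asks whether a locus interval overlaps a
reference simple-repeat record (units pre-filtered to 3–8 bp) with an
equivalent unit. The default equivalence is canonical equality — rotations
*and* reverse complements — because repeat phase is arbitrary between
tools; a strict reverse-complement-only mode (`revcomp_only`) reproduces
literal exact-string matching. A locus matching several records counts
once.

## Disease screen

The shipped catalog (`trlandscape/data/disease_catalog.yaml`, GRCh37)
covers ten repeat-expansion disease loci. Observed motifs at a catalog
locus fall into four categories by canonical comparison: *reference motif =
disease motif* (shared-motif loci such as FRDA), *reference motif only*
and *disease motif only* (mutated-motif loci such as CANVAS, where disease
requires AAGGG in place of the reference AAAAG), and *neither* (novel
motifs, e.g. AAACT at SCA31). Estimated repeats = estimated bases / motif
length, real-valued and reported to one decimal; the pathogenic flag is a
`≥ pathogenic_min_repeats` comparison, assessed only when the observed
motif matches the disease motif and a threshold exists. Thresholds are
literature-derived configuration, not measurements; where sources disagree
(ALS: 30 vs 60 repeats) the conservative bound is used and the contested
one recorded.

## Synthetic-data generator

The generator emulates the study conditions rather than read-level data:

- **Genome**: two contigs, 10 Mb total by default; the region track tiles
  the genome in 5 kb blocks labeled intergenic/intron/promoter/exon/TTS at
  configurable proportions (a stylized annotation — no gene structure);
  Alu elements are non-overlapping 300 bp intervals covering 11% ± 1% of
  the genome.
- **Cohort**: 200 genomes at depth ~N(40, 3) fold-coverage (clipped at
  10×); 400 planted loci, 75% rare — rare carrier counts uniform between 1
  and the 1% cutoff, common frequencies uniform on [0.02, 0.5].
- **Alu enrichment** is planted by giving every locus the same Bernoulli
  probability q of overlapping an Alu, with q solved numerically so the
  expected contingency table reproduces the target odds ratio (1.56 by
  default); non-overlapping placements are rejection-sampled from Alu-free
  space. This makes the planted OR exact in expectation and recoverable by
  the enrichment module.
- **Motifs** follow a configurable composition (75% two-nucleotide units,
  A&G-dominated pairs, modal length 4 bp), drawn as random primitive units
  and stored canonically.
- **Counts**: carrier allele lengths are log-uniform on [176, 2000] bp — a
  modeling choice, since the carrier length distribution is not otherwise
  constrained — inverted through the length model to an intended count
  (optionally plus integer Gaussian noise, default 0), emitted as a raw
  count at the sample's own depth and normalized back. Normalized values
  are rounded at the 9-decimal emission precision so the depth round trip
  is exact and noise-free runs reproduce the planted truth bit-for-bit.
  Non-carriers receive sporadic background counts from {0, 1, 2}, well
  below the presence threshold.
- **Reference origin**: 85% of loci (configurable, within the 76–90% band
  typical of real cohorts) receive an overlapping simple-repeat record
  whose unit is a random rotation and/or reverse complement of the locus
  motif; background records are placed away from all loci so non-origin
  loci match nothing.

What the generator does **not** emulate: sequence context, repeat
interruptions/purity, locus-length miscalibration, population structure,
batch effects between sequencing platforms, or the heavy-tailed per-genome
outliers seen in real cohorts. Passing tests therefore demonstrate that
the *analysis machinery* is correct against planted truth, not that any
particular biological claim holds in real data.

All randomness flows from a single seed; per-stage substreams (seeded by
stage name) keep outputs stable when unrelated stages change, and
identical configurations produce byte-identical bundles.

## Numerical and design choices

- One coordinate convention (0-based half-open) end to end; UCSC
  SimpleRepeats `chromStart` is already 0-based and adopted as-is.
- Quartiles/IQR use linear interpolation (Q3 − Q1).
- Locus merging across samples requires identical motif strings and
  overlap within `max_gap` (default 0: strict overlap), spanning the union.
- The exhaustive Fisher validation enumerates every 2×2 table with grand
  total ≤ 30 against an exact-rational hypergeometric enumerator.
- Experiment sizes in the test and acceptance suites (200-genome cohorts,
  5,000-locus odds-ratio plantings over 20 seeds, 1,000-iteration
  saturation) are desk-scale choices that keep Monte-Carlo error small
  relative to the tolerances being checked.

## Known limitations

- No allele-level genotyping: presence and size estimates describe the
  larger allele at best.
- Region assignment is annotation-track-driven; no transcript model is
  built, so promoter/TTS windows are whatever the supplied track encodes.
- The genomic-space Fisher adjustment is the bedtools model — a coarse
  dart-throwing approximation whose trial count depends on mean interval
  lengths; it is used for comparability with the established tool, not as
  an optimal test.
- Catalog coordinates and thresholds are configuration shipped for
  convenience and should be reviewed before clinical-adjacent use.
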