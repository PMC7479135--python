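"""Screen a cohort at known repeat-expansion disease loci.

Plants a FRDA-like GAA expansion of 101 repeats in one genome and a
CANVAS-like mutated-motif (AAGGG) expansion in another, then screens the
matrix: counts are converted to repeat numbers via bases = 140.6 + 7.7x and
compared to the catalog's pathogenic thresholds.  For recessive loci a flag
means carrier-compatible only - anchored IRR counts cannot separate the two
alleles.
"""

import trlandscape as tl

bundle = tl.simulate_bundle(tl.SimConfig(seed=1))
catalog = tl.synthetic_disease_catalog(bundle.layout)
frda = next(d for d in catalog if d.code == "SYN_FRDA")
canvas = next(d for d in catalog if d.code == "SYN_CANVAS")

matrix, manifest = tl.plant_disease_expansion(
    bundle.matrix, bundle.manifest, frda, bundle.matrix.samples[0], repeats=101
)
matrix, manifest = tl.plant_disease_expansion(
    matrix, manifest, canvas, bundle.matrix.samples[1], repeats=450
)

for r in tl.screen_cohort(matrix, catalog):
    if r.start not in (frda.start, canvas.start):
        continue
    flag = {True: "PATHOGENIC-RANGE", False: "below threshold", None: "not assessable"}
    print(
        f"{r.disease_code:11s} {r.sample}: motif {r.observed_motif} "
        f"({r.motif_category}), ~{r.estimated_repeats:.0f} repeats "
        f"-> {flag[r.pathogenic]}"
        + ("  [recessive: carrier interpretation only]" if r.carrier_only else "")
    )
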