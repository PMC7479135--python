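"""Simulate a cohort and classify its large TRs into rare and common.

Builds the default synthetic cohort (200 genomes, 400 planted loci, 40x
mean depth), calls presence at the 5-read threshold (~175 bp under the
length model) and splits loci at the 1% cohort-frequency boundary.
"""

import trlandscape as tl

bundle = tl.simulate_bundle(tl.SimConfig(seed=1))
presence = tl.call_presence(bundle.matrix, threshold=5)
classes = tl.classify_frequency(presence, rare_fraction=0.01)

print(f"cohort: {bundle.matrix.n_loci} loci x {bundle.matrix.n_samples} genomes")
print(f"rare loci:   {classes.n_rare}  (present in < {classes.cutoff} genomes)")
print(f"common loci: {classes.n_common}  (present in >= {classes.cutoff} genomes)")

counts, summary = tl.per_genome_counts(presence, classes.classes)
print("\nlarge TRs per genome (median [Q1-Q3]):")
for label in ("rare", "common"):
    row = summary.loc[label]
    print(f"  {label:7s} {row['median']:.0f} [{row['q1']:.0f}-{row['q3']:.0f}]")

spectrum = tl.occurrence_spectrum(presence)
print(
    f"\n{100 * spectrum.singleton_fraction:.0f}% of loci are singletons "
    "(seen in exactly one genome) - typical of a rare-dominated landscape."
)
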