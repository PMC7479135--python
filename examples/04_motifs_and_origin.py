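"""Motif composition of the TR landscape and its reference-repeat origin.

Motifs are canonicalized (smallest string over rotations and the reverse
complement) so e.g. GGGGCC and CCCCGG are one motif; composition is profiled
by unique-nucleotide count, nucleotide pair and unit length, and each locus
is checked for an overlapping reference simple repeat with an equivalent
unit.
"""

import trlandscape as tl

bundle = tl.simulate_bundle(tl.SimConfig(seed=1))
motifs = [l.motif for l in bundle.matrix.loci]

tables = tl.motif_profile_tables({"dataset": motifs})
uniq = tables["unique_nucleotides"]["dataset"]
print(f"motifs with 2 unique nucleotides: {100 * uniq[2]:.0f}%")
pair = tables["pair_class"]["dataset"]
print(f"A&G-composed motifs:              {100 * pair['A&G']:.0f}%")
length = tables["motif_length"]["dataset"]
print(f"modal motif length:               {length.idxmax()} bp "
      f"({100 * length.max():.0f}% of motifs)")

calls = tl.match_references(bundle.matrix.loci, bundle.simple_repeats)
frame = tl.percent_from_reference(calls)
print(
    f"\n{frame.loc['all', 'percent']:.1f}% of large TRs overlap a reference "
    "simple repeat with a matching (strand/phase-equivalent) motif - these "
    "are expansions of repeats already in the reference genome."
)
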