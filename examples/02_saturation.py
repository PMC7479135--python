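"""Discovery saturation: how many new large TRs does each extra genome add?

Common loci saturate quickly (every genome carries most of them); rare loci
keep being discovered, and the tail slope of the permutation curve is the
expected number of novel loci per additional genome.
"""

import trlandscape as tl
from trlandscape.saturation import residual_discovery_rate, saturation_curve

bundle = tl.simulate_bundle(tl.SimConfig(seed=1))
presence = tl.call_presence(bundle.matrix)
classes = tl.classify_frequency(presence)

for label in ("common", "rare"):
    sub = presence.restrict(classes.classes == label)
    curve = saturation_curve(sub, n_iterations=1000, seed=7, label=label)
    rate = residual_discovery_rate(curve, k_last=15)
    half = next(
        i + 1 for i, v in enumerate(curve.mean_cumulative) if v >= 0.95 * curve.final
    )
    print(
        f"{label:7s} {curve.final:5.0f} loci total; 95% found after {half} genomes; "
        f"residual rate {rate:.2f} novel loci per additional genome"
    )
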