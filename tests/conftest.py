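import pytest

import trlandscape as tl


@pytest.fixture(scope="session")
def bundle():
    """Default noise-free synthetic cohort (200 genomes, 400 planted loci)."""
    return tl.simulate_bundle(tl.SimConfig(seed=11))


@pytest.fixture(scope="session")
def presence(bundle):
    return tl.call_presence(bundle.matrix)
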