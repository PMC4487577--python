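import pytest

from divergene import synthio


@pytest.fixture(scope="session")
def small_spec() -> synthio.SynthSpec:
    return synthio.SynthSpec(seed=1, n_families=30)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    """One generated P/G transcriptome pair shared across read-only tests."""
    p_set, g_set, truth = synthio.generate_transcriptomes(small_spec)
    return p_set, g_set, truth
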