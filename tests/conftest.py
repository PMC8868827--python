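import pytest

from hrcoreg import normalize, synthetic


@pytest.fixture(scope="session")
def default_study():
    """One default-condition simulated study (11 normal + 38 tumor)."""
    return synthetic.simulate_nanostring_study(seed=11)


@pytest.fixture(scope="session")
def normalized(default_study):
    """The default study pushed through the full normalization chain."""
    return normalize.normalize_pipeline(
        default_study.counts, default_study.samples
    )
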