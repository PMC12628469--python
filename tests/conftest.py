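import numpy as np
import pytest

from glimmer.simulate import make_reconstruction_fixture


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic 25-patient reconstruction table."""
    return make_reconstruction_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20250926)
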