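import numpy as np
import pytest

from fracstab import sample_fixtures


@pytest.fixture(scope="session")
def parameter_triples():
    """Reproducible (alpha1, rho, a) draws shared across property tests."""
    return sample_fixtures(seed=20260921, n=50)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
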