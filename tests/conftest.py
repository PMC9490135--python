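import numpy as np
import pytest

from sagecort.synthetic import SyntheticConfig, generate

@pytest.fixture(scope="session")
def small_dataset():
    """One fixed small synthetic population shared across tests."""
    return generate(SyntheticConfig(n_birds=120, seed=20240601))


@pytest.fixture(scope="session")
def medium_dataset():
    """A larger population for recovery checks."""
    return generate(SyntheticConfig(n_birds=1200, seed=777))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
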