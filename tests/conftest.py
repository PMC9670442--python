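import numpy as np
import pytest

from cardiov import load_mapping
from cardiov.experiments import TINY_DEEP_CONFIG
from cardiov.model import CardioVNet
from cardiov.synthetic import generate_dataset


@pytest.fixture(scope="session")
def mapping_table():
    return load_mapping()


@pytest.fixture(scope="session")
def small_dataset():
    """Balanced 40-record synthetic set with metadata (session-cached)."""
    return generate_dataset(n_per_class=10, seed=123)


@pytest.fixture(scope="session")
def tiny_deep_net():
    """Untrained 7-stage narrow network (session-cached; inference only —
    tests that mutate parameters must build their own)."""
    return CardioVNet(TINY_DEEP_CONFIG, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
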