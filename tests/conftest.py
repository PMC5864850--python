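import numpy as np
import pytest

from pvpsvm import acceptance_scenario, encode_set, generate
from pvpsvm.properties import default_tables


@pytest.fixture(scope="session")
def tables():
    return default_tables()


@pytest.fixture(scope="session")
def small_dataset():
    """30-sample synthetic labeled set with a strong compositional signal."""
    scenario = acceptance_scenario(seed=11)
    scenario = type(scenario)(**{**scenario.__dict__, "n_pos": 10, "n_neg": 20})
    return generate(scenario)


@pytest.fixture(scope="session")
def small_encoded(small_dataset):
    X, y = encode_set(small_dataset)
    return X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(58321)
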