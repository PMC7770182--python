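import numpy as np
import pytest

from grnforest import generate_network, make_dataset, smooth_dataset


@pytest.fixture(scope="session")
def small_model():
    """A stable 5-gene / 6-edge linear network."""
    return generate_network(5, 6, seed=3)


@pytest.fixture(scope="session")
def small_dataset(small_model):
    """5 experiments x 21 points plus full wild-type/KO/KD statics."""
    return make_dataset(small_model, n_experiments=5, n_timepoints=21, seed=4)


@pytest.fixture(scope="session")
def smoothed_small(small_dataset):
    return smooth_dataset(small_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
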