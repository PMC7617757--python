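import numpy as np
import pytest

from oxyregulon import ChannelLayout, ModelParameters, NoiseModel


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def small_layout():
    """A quick layout for unit tests: 12 trenches of 3 cells."""
    return ChannelLayout(n_trenches=12, cells_per_trench=3)


@pytest.fixture(scope="session")
def noise_off():
    return NoiseModel.off()


@pytest.fixture(scope="session")
def default_noise():
    return NoiseModel()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
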