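import numpy as np
import pytest

from plaidobs.direction_model import DirectionGrid, SensoryParams, StimulusConfig


@pytest.fixture(scope="session")
def grid():
    return DirectionGrid()


@pytest.fixture()
def stim():
    return StimulusConfig(A_L=0.4)


@pytest.fixture()
def sens():
    return SensoryParams(sigma_S=15.0, sigma_L=10.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
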