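import numpy as np
import pytest

from pursuitmon.io import StudyConfig
from pursuitmon.synth import make_montage, make_study
from pursuitmon.timefreq import channel_adjacency


@pytest.fixture(scope="session")
def montage16():
    return make_montage(16)


@pytest.fixture(scope="session")
def adjacency16(montage16):
    return channel_adjacency(montage16)


@pytest.fixture(scope="session")
def montage60():
    return make_montage(60)


@pytest.fixture(scope="session")
def config():
    return StudyConfig()


@pytest.fixture(scope="session")
def small_study():
    """4 subjects x 6 trials of the plain tracking task, behavioral only."""
    return make_study(n_subjects=4, task=1, seed=11, n_trials=6)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
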