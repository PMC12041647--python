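import numpy as np
import pytest

from mctperf.containers import AIFModel
from mctperf.phantom import gamma_variate, make_phantom, simulate_ctp


@pytest.fixture(scope="session")
def aif_model():
    return AIFModel()


@pytest.fixture(scope="session")
def fine_grid():
    return np.arange(0.0, 60.0, 0.5)


@pytest.fixture(scope="session")
def aif_curve(aif_model, fine_grid):
    return gamma_variate(fine_grid, aif_model)


@pytest.fixture(scope="session")
def phantom():
    return make_phantom(shape=(2, 64, 64), seed=11)


@pytest.fixture(scope="session")
def noiseless_series(phantom):
    return simulate_ctp(phantom, noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def noisy_series(phantom):
    return simulate_ctp(phantom, noise_sd=2.0, seed=11)
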