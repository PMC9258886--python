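import numpy as np
import pytest

from cortexfold import ModelParameters, SimulationConfig, run_simulation
from cortexfold.synthetic import SyntheticConfig, generate_profile_dataset


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def bar_frames():
    """Default calibrated bar run (60 elements, dt = 0.05 d)."""
    cfg = SimulationConfig(geometry="bar", n_elems=60, dt=0.05)
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Noise-free synthetic dataset at the calibrated parameter values."""
    cfg = SyntheticConfig(noise="none", dt=0.1)
    return generate_profile_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
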