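import numpy as np
import pytest

from soilncycle.synthetic_data import NoiseModel, SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def silent_bundle():
    """One full simulated study with all noise and spatial effects at zero."""
    return simulate_study(SimulationConfig(noise=NoiseModel.silent(), seed=11))


@pytest.fixture(scope="session")
def noisy_bundle():
    """One full simulated study under the default noise model."""
    return simulate_study(SimulationConfig(seed=23))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
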