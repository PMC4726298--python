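import pytest

from telolnc.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic study shared across tests."""
    return simulate_dataset(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def zero_noise_dataset():
    """Noise-free study: planted labels must be recovered exactly."""
    return simulate_dataset(SimulationConfig(seed=11, noise_sigma=0.0))
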