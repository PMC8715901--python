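import numpy as np
import pytest

from gamemarkers import RoomConfig, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def room() -> RoomConfig:
    return RoomConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """Six simulated participants at default settings, fixed seed."""
    return simulate_cohort(SimulationConfig(n_participants=6, seed=42))


@pytest.fixture(scope="session")
def noise_free_cfg() -> SimulationConfig:
    return SimulationConfig(seed=0).noise_free()
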