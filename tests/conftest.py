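import numpy as np
import pytest

from mdtsim import MagnetSpec, SimulationConfig, calibrate_to_target
from mdtsim.config import default_config


@pytest.fixture(scope="session")
def calibrated_magnet() -> MagnetSpec:
    """Default implant calibrated to 0.5 T and 180 T/m at the vessel centre."""
    base = MagnetSpec(b_rem=2.0, center=(0.02, -0.02), width=0.0036,
                      height=0.020)
    return calibrate_to_target(base, (0.02, 0.002), 0.5, 180.0)


@pytest.fixture(scope="session")
def default_run_config(calibrated_magnet) -> SimulationConfig:
    from dataclasses import replace

    return replace(SimulationConfig(seed=1), magnet=calibrated_magnet)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
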