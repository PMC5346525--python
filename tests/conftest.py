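import numpy as np
import pytest

from connectodyn import SimulationConfig


@pytest.fixture(scope="session")
def tiny_sim() -> SimulationConfig:
    """Small cohort exercising every pipeline stage quickly."""
    return SimulationConfig(
        n_patients=6,
        n_controls=6,
        n_regions=12,
        n_volumes=64,
        n_blocks=3,
        gm_shape=(18, 18, 21),
        n_parcels=12,
        seed=42,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
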