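import numpy as np
import pytest

from emorsa import synthdata as sd


@pytest.fixture
def spec():
    return sd.DesignSpec()


@pytest.fixture
def world():
    """Small planted world with a 33-voxel spherical signal region."""
    center = np.array([5, 5, 5])
    offsets = np.array(
        [
            (dx, dy, dz)
            for dx in range(-2, 3)
            for dy in range(-2, 3)
            for dz in range(-2, 3)
            if dx * dx + dy * dy + dz * dz <= 4
        ]
    )
    return sd.PlantedWorld(
        seed=7,
        idiosyncrasy_sd=0.1,
        noise_sd=0.0,
        signal_region=center + offsets,
        grid_shape=(11, 11, 11),
        voxel_size_mm=(3.0, 3.0, 3.0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
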