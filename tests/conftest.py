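import numpy as np
import pandas as pd
import pytest

from pasquant import physics
from pasquant.imaging import ImageCalibration
from pasquant.quantify import SamplerConfig


@pytest.fixture
def env():
    return physics.AirEnvironment(temperature=293.0)


@pytest.fixture
def material():
    return physics.MaterialProperties(
        density_g_cm3=2.8, volume_shape_factor=1.6, dynamic_shape_factor=1.4
    )


@pytest.fixture
def identity_material():
    return physics.MaterialProperties(
        density_g_cm3=1.0, volume_shape_factor=1.0, dynamic_shape_factor=1.0
    )


@pytest.fixture
def calib():
    return ImageCalibration(pixels_per_micron=1.71, image_width_um=450.0, image_height_um=600.0)


@pytest.fixture
def sampler():
    return SamplerConfig()


@pytest.fixture
def random_particle_table():
    """Factory for random particle tables keyed by seed."""

    def make(seed: int, n: int = 200, d_lo: float = 0.3, d_hi: float = 30.0) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        d = np.exp(rng.uniform(np.log(d_lo), np.log(d_hi), size=n))
        return pd.DataFrame(
            {
                "image_id": "rand",
                "particle_id": np.arange(1, n + 1),
                "area_um2": np.pi * (d / 2) ** 2,
                "d_pa_um": d,
                "x_um": rng.uniform(0, 450, n),
                "y_um": rng.uniform(0, 600, n),
                "touches_edge": False,
            }
        )

    return make
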