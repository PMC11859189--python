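import numpy as np
import pytest

from lagoonwq.radiometry import AtmosphericTerms
from lagoonwq.synthetic import (
    SimulationConfig,
    default_atmosphere,
    default_calibration,
    simulate_field_campaign,
    simulate_scene,
)


@pytest.fixture(scope="session")
def atmosphere():
    return default_atmosphere()


@pytest.fixture(scope="session")
def calibration(atmosphere):
    return default_calibration(atmosphere)


@pytest.fixture(scope="session")
def simple_terms():
    """Single set of terms replicated over the 4 bands, easy to hand-check."""
    return AtmosphericTerms(
        path_radiance=20.0,
        solar_irradiance=1500.0,
        gas_transmittance=0.95,
        total_transmittance=0.8,
        spherical_albedo=0.15,
    )


@pytest.fixture(scope="session")
def campaign_1000():
    """Large synthetic field campaign for moment/correlation checks."""
    return simulate_field_campaign(SimulationConfig(n_samples=1000, seed=1))


@pytest.fixture(scope="session")
def noiseless_bundle(atmosphere, calibration):
    """A noise-free simulated scene with truth rasters."""
    cfg = SimulationConfig(
        seed=3, noise_cv=0.0, scene_shape=(100, 100), water_fraction=0.6
    )
    return simulate_scene(cfg, atmosphere, calibration)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
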