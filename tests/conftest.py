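import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mdflow import Recording, SimConfig, simulate
from mdflow.fixtures import FixtureConfig, generate_subject


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_recording():
    """10-channel noise mixture of 3 bistable latents, 60 s at 100 Hz."""
    cfg = FixtureConfig(
        n_channels=10,
        n_latent=3,
        noise_sigma=0.2,
        duration_s=60.0,
        fs=100.0,
        mixing_seed=11,
        drive_seed=7,
        condition="test",
    )
    return generate_subject(cfg)


@pytest.fixture(scope="session")
def short_sim():
    """Two-variable bistable run, 50 time units, moderate noise."""
    return simulate(SimConfig(n_vars=2, noise_sigma=0.2, dt=0.01, t_end=50.0, seed=3))
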