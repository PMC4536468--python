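import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_cell():
    """Small noise-free simulated cell with known R = 1.12 and no oscillation."""
    from spindlemetrics import SimConfig, simulate_cell

    cfg = SimConfig(
        noise_sigma_um=0.0,
        osc_amplitude_um=0.0,
        r_true=1.12,
        r_sigma=0.0,
        duration_s=30.0,
        seed=42,
    )
    return simulate_cell(cfg, 0)


@pytest.fixture
def noisy_cohort():
    """Ten noisy cells at default study conditions, short recording."""
    from spindlemetrics import SimConfig, simulate_cohort

    cfg = SimConfig(n_cells=10, duration_s=60.0, seed=7)
    return simulate_cohort(cfg)
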