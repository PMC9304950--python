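import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import twinwaves as tw

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Two-measure five-wave cohort with sex effect, small enough for fast tests."""
    cfg = tw.SimulationConfig(
        n_mz_pairs=300, n_dz_pairs=400, n_waves=5,
        measures=["anxiety", "conduct"], sex_effect=0.3,
        wave_mean_shifts=[0.0, 0.2, 0.15, 0.1, 0.1], seed=11)
    return tw.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def big_twowave_cohort():
    """Large two-wave cohort at the default variance components."""
    cfg = tw.SimulationConfig(
        n_mz_pairs=5000, n_dz_pairs=5000, n_waves=2, measures=["x"], seed=21)
    return tw.simulate_cohort(cfg)
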