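"""Shared fixtures: synthetic trials reused across the suite (session scope,
so the expensive ones are simulated and analyzed only once)."""

import numpy as np
import pytest

import gaitspan as gs
from gaitspan.pipeline import analyze_trial


@pytest.fixture(scope="session")
def trial_05():
    """Noisy 0.5 m/s trial, 60 s, seed 1."""
    return gs.simulate_trial(gs.preset("sci_0.5", rng_seed=1, trial_duration=60.0))


@pytest.fixture(scope="session")
def trial_05_clean():
    """Noise-free, bias-free 0.5 m/s trial (zero-noise oracle world)."""
    return gs.simulate_trial(gs.preset(
        "sci_0.5", rng_seed=3, trial_duration=60.0,
        acc_noise_sd=0.0, gyro_noise_sd=0.0, gyro_bias=0.0))


@pytest.fixture(scope="session")
def trial_05_frozen():
    """Noise-free, jitter-free trial: every cycle identical."""
    return gs.simulate_trial(gs.preset(
        "sci_0.5", rng_seed=4, trial_duration=60.0, jitter_cv_duration=0.0,
        acc_noise_sd=0.0, gyro_noise_sd=0.0, gyro_bias=0.0))


@pytest.fixture(scope="session")
def analysis_05(trial_05):
    return analyze_trial(trial_05.imu_left, trial_05.imu_right)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
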