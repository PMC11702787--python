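"""Shared fixtures: stimulus movies at two resolutions and a calibrated
noise level, all generated programmatically (session-scoped because movie
rendering and calibration dominate suite runtime)."""

from __future__ import annotations

import pytest

import logprf
from logprf.fitting import FitConfig, PredictionEngine


@pytest.fixture(scope="session")
def hrf():
    return logprf.default_hrf()


@pytest.fixture(scope="session")
def warp():
    return logprf.WarpParams()  # k=5, r_max=8


@pytest.fixture(scope="session")
def grid54():
    return logprf.VisualFieldGrid(54)


@pytest.fixture(scope="session")
def movies54(grid54, warp):
    """Quick low-resolution fixed/log movie pair (direct 54-px render)."""
    fixed = logprf.generate_fixed_bar_movie(logprf.SweepSchedule(), grid54, seed=1)
    logm = logprf.generate_log_bar_movie(fixed, warp)
    return fixed, logm


@pytest.fixture(scope="session")
def movies108(warp):
    """Production-style pair: rendered at 540 px, warped, downsampled to
    the standard 108-px fitting resolution."""
    grid = logprf.VisualFieldGrid(540)
    fixed = logprf.generate_fixed_bar_movie(logprf.SweepSchedule(), grid, seed=1)
    logm = logprf.generate_log_bar_movie(fixed, warp)
    return (
        logprf.preprocess_movie(fixed, 108, fixed.n_frames),
        logprf.preprocess_movie(logm, 108, logm.n_frames),
    )


@pytest.fixture(scope="session")
def engine_log108(movies108, hrf):
    eng = PredictionEngine(movies108[1], hrf, 1.2)
    eng.build_seed_bank()
    return eng


@pytest.fixture(scope="session")
def engine_fixed108(movies108, hrf):
    eng = PredictionEngine(movies108[0], hrf, 1.2)
    eng.build_seed_bank()
    return eng


@pytest.fixture(scope="session")
def calibrated_sd(movies108, hrf):
    """Noise sd calibrated to 42% mean retained VE on the fixed-bar
    stimulus (reduced 150-pRF calibration subsample)."""
    noise = logprf.calibrate_noise(
        logprf.build_ground_truth(),
        movies108[0],
        hrf,
        target_mean_ve=0.42,
        seed=11,
        n_calibration=150,
        tol=0.01,
    )
    return noise.sd


@pytest.fixture(scope="session")
def fit_config():
    return FitConfig()
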