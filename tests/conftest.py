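"""Shared simulated-experiment fixtures.

Simulation is cheap (a fraction of a second per plate), so fixtures hold
full analyzed runs at session scope and tests interrogate them. Seed blocks
are fixed per fixture so the suite is deterministic.
"""

import numpy as np
import pytest

from monodplate.pipeline import RunConfig, analyze_run, simulate_run

ZERO_NOISE = {"well_scale_cv": 0.0, "read_cv": 0.0,
              "gfp_read_cv": 0.0, "day_scale_cv": 0.0}


def _run(seed, **kwargs):
    cfg = RunConfig(mode="full", seed=seed, out="unused", bootstrap_reps=0,
                    **kwargs)
    datasets = simulate_run(cfg)
    return cfg, datasets, analyze_run(datasets, cfg)


@pytest.fixture(scope="session")
def zero_noise_run():
    """One noiseless nitrogen run, calibration + reporter panels."""
    return _run(1, noise=dict(ZERO_NOISE),
                panels=("calibration", "reporter"))


@pytest.fixture(scope="session")
def nitrogen_runs():
    """Twenty default-noise nitrogen calibration-panel runs (seeds
    1001-1020); the half-saturation estimate is noisy per run, so averages
    use a generous number of repeat experiments."""
    return [_run(seed, panels=("calibration",)) for seed in range(1001, 1021)]


@pytest.fixture(scope="session")
def glucose_runs():
    """Six default-noise glucose calibration-panel runs (seeds 2001-2006)."""
    return [_run(seed, nutrient="glucose", panels=("calibration",))
            for seed in range(2001, 2007)]


@pytest.fixture(scope="session")
def reporter_runs():
    """Five default-noise nitrogen runs with the reporter panel
    (seeds 3001-3005)."""
    return [_run(seed, panels=("calibration", "reporter"))
            for seed in range(3001, 3006)]
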