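import numpy as np
import pytest

from funcest import gp, stimuli, traces
from funcest.gp import FitConfig, GPHyperParams
from funcest.stimuli import DesignCell, DrawerProfile


def sample_gp_function(theta: GPHyperParams, seed: int, n: int = 40) -> traces.ResponseFunction:
    """Draw one function from the GP prior (with observation noise) on the
    fixed response grid — the generative counterpart of the measurement
    model, used for parameter-recovery checks."""
    grid = traces.response_grid(n)
    K = gp.kernel_matrix(grid, grid, theta, include_noise=True)
    L = np.linalg.cholesky(K + 1e-12 * np.eye(n))
    y = L @ np.random.default_rng(seed).standard_normal(n)
    return traces.ResponseFunction(grid, y)


SMOOTH_THETA = GPHyperParams(2.0, 1.0, 0.1)
TRACKING_THETA = GPHyperParams(0.05, 1.0, 1e-6)


def fit_style_battery(problems, n_per_style, fit_config, master_seed=0):
    """Simulate smooth and tracking drawers on each problem and fit the
    measurement model; returns list of (problem_id, style, record)."""
    out = []
    for k, cell in enumerate(problems):
        stim = stimuli.make_stimulus(
            cell, stimuli.default_coefficients(cell.generator), 0.15,
            seed=master_seed * 977 + k,
        )
        for style, theta in (("smooth", SMOOTH_THETA), ("tracking", TRACKING_THETA)):
            for j in range(n_per_style):
                tr = stimuli.simulate_drawer(
                    stim,
                    DrawerProfile(theta_true=theta, motor_sd=0.01),
                    n_raw_points=120,
                    seed=master_seed * 104729 + k * 1009 + j * 2 + (style == "smooth"),
                    participant_id=f"{style}{j:02d}",
                )
                rf = traces.process_trace(tr)
                rec = gp.fit_hyperparams(rf, fit_config)
                out.append((cell.problem_id, style, rec))
    return out


@pytest.fixture(scope="session")
def style_records_one_problem():
    """30 smooth + 30 tracking simulated drawers on one problem, fitted."""
    cell = DesignCell("linear", 6, "large", 1)
    return fit_style_battery([cell], 30, FitConfig(n_restarts=3, seed=0), master_seed=1)
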