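import numpy as np
import pytest

import runpause as rp


@pytest.fixture
def unit_steps():
    """Constant unit step length (lambda = 1)."""
    return rp.constant_steps(1.0)


@pytest.fixture
def motion_start():
    return rp.InitialState(1.0)


@pytest.fixture
def waiting_start():
    return rp.InitialState(0.0)


@pytest.fixture
def slow_restart_rates():
    """The long-pause parameter set used throughout the single-filament
    discussion: frequent pausing, very slow restart."""
    return rp.TransitionRates(kappa_w=0.1, kappa_m=0.001)


def random_rates(rng, include_boundaries=False):
    """Draw transition rates, optionally snapping to {0, 1} boundaries."""
    kw, km = rng.random(2)
    if include_boundaries:
        snap = rng.random(2)
        if snap[0] < 0.15:
            kw = float(rng.integers(0, 2))
        if snap[1] < 0.15:
            km = float(rng.integers(0, 2))
    return rp.TransitionRates(kw, km)


def max_sigma_gap(sim, analytic_msd):
    """Largest |simulated - exact| in units of the ensemble standard error.

    Steps with zero spread (deterministic displacement) must agree exactly
    and are excluded from the ratio.
    """
    exact = analytic_msd[sim.steps - 1]
    diff = np.abs(sim.msd - exact)
    zero = sim.stderr == 0.0
    if np.any(diff[zero] > 1e-9):
        return np.inf
    if np.all(zero):
        return 0.0
    return float(np.max(diff[~zero] / sim.stderr[~zero]))
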