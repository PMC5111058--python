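"""Parameter-space scans over (kappa_w, kappa_m) and unit conversions.

Crossover-time scans run the exact MSD engine per grid cell, compute the
running exponent, and apply the sustained crossover criterion; cells whose
exponent has not settled within the horizon are flagged (the stored value is
the horizon, a lower bound — never interpolated).  D_inf scans evaluate the
closed form directly.

Physical time enters through one convention: every discrete tick — motion or
wait — lasts the motion-step duration <l>/v (8 nm at 1 um/s is 8 ms per
step; a 100 nm mesh at 1 um/s is 0.1 s per step).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exponent import DEFAULT_EPSILON, alpha_series, crossover_time
from .model import (
    InitialState,
    ParameterError,
    PhaseGrid,
    StepLengthModel,
    TransitionRates,
    constant_steps,
    custom_steps,
    persistence_model,
)
from .network_analytic import (
    asymptotic_diffusion,
    initial_exponent_network,
    msd_network,
)
from .single_analytic import initial_exponent_single, msd_single

__all__ = [
    "scan",
    "constrained_slice",
    "steps_to_time",
    "time_to_steps",
    "QUANTITIES",
]

QUANTITIES = ("n_c_single", "n_c_network", "D_inf")


def _steps_model(lambda_het: float, mean_step: float) -> StepLengthModel:
    if lambda_het == 1.0:
        return constant_steps(mean_step)
    return custom_steps(mean_step, lambda_het * mean_step**2)


def _cell_value(
    quantity: str,
    rates: TransitionRates,
    init: InitialState,
    steps: StepLengthModel,
    A: float,
    epsilon: float,
    n_max: int,
    v: float,
) -> tuple[float, bool]:
    if quantity == "D_inf":
        model = persistence_model(rates, init, steps, A)
        return asymptotic_diffusion(model, v), True
    if quantity == "n_c_single":
        msd = msd_single(rates, init, steps, n_max)
        target = 2.0
    elif quantity == "n_c_network":
        msd = msd_network(persistence_model(rates, init, steps, A), n_max)
        target = 1.0
    else:
        raise ParameterError(f"unknown quantity {quantity!r}; choose from {QUANTITIES}")
    if np.any(msd.msd <= 0.0):
        return float(n_max), False
    res = crossover_time(alpha_series(msd), target, epsilon)
    if not res.converged:
        return float(n_max), False
    return float(res.n_c), True


def scan(
    quantity: str,
    kappa_w_values: Sequence[float],
    kappa_m_values: Sequence[float],
    *,
    A: float = 0.0,
    lambda_het: float = 1.0,
    q_m0: float = 1.0,
    epsilon: float = DEFAULT_EPSILON,
    n_max: int = 4096,
    v: float = 1.0,
    mean_step: float = 1.0,
) -> PhaseGrid:
    """Scan a quantity over the (kappa_w, kappa_m) grid.

    ``matrix[i, j]`` holds the value at ``(kappa_w_values[i],
    kappa_m_values[j])``.  For crossover quantities, non-converged cells are
    flagged in ``converged`` and hold the horizon n_max as a lower bound.
    """
    kw_vals = np.asarray(kappa_w_values, dtype=float)
    km_vals = np.asarray(kappa_m_values, dtype=float)
    if kw_vals.size == 0 or km_vals.size == 0:
        raise ParameterError("grid axes must be non-empty")
    if np.any(kw_vals < 0) or np.any(kw_vals > 1) or np.any(km_vals <= 0) or np.any(km_vals > 1):
        raise ParameterError("grid values must lie in (0, 1] (kappa_w may be 0)")
    init = InitialState(q_m0)
    steps = _steps_model(lambda_het, mean_step)
    matrix = np.empty((kw_vals.size, km_vals.size))
    converged = np.ones(matrix.shape, dtype=bool)
    for i, kw in enumerate(kw_vals):
        for j, km in enumerate(km_vals):
            rates = TransitionRates(kw, km)
            matrix[i, j], converged[i, j] = _cell_value(
                quantity, rates, init, steps, A, epsilon, n_max, v
            )
    return PhaseGrid(
        kappa_w_values=kw_vals,
        kappa_m_values=km_vals,
        matrix=matrix,
        quantity=quantity,
        converged=converged,
        metadata={
            "A": A,
            "lambda_het": lambda_het,
            "q_m0": q_m0,
            "epsilon": epsilon,
            "n_max": n_max,
            "v": v,
            "mean_step": mean_step,
        },
    )


def constrained_slice(
    quantity: str,
    kappa_w_values: Sequence[float],
    *,
    A: float = 0.0,
    lambda_het: float = 1.0,
    q_m0: float = 1.0,
    epsilon: float = DEFAULT_EPSILON,
    n_max: int = 4096,
    v: float = 1.0,
    mean_step: float = 1.0,
) -> pd.DataFrame:
    """One-parameter slice kappa_m = 1 - kappa_w of the phase diagram.

    On this slice the relaxation factor vanishes, so the occupancy
    equilibrates after a single step: the initial exponent is independent of
    q_m0 and D_inf is a function of kappa_w alone (s = 1 - kappa_w).

    Supported quantities: those of :func:`scan` plus ``alpha_star_single``
    and ``alpha_star_network``.
    """
    kw_vals = np.asarray(kappa_w_values, dtype=float)
    if np.any(kw_vals <= 0) or np.any(kw_vals >= 1):
        raise ParameterError("slice requires kappa_w strictly inside (0, 1)")
    init = InitialState(q_m0)
    steps = _steps_model(lambda_het, mean_step)
    rows = []
    for kw in kw_vals:
        rates = TransitionRates(kw, 1.0 - kw)
        if quantity == "alpha_star_single":
            value, conv = initial_exponent_single(rates, init, steps), True
        elif quantity == "alpha_star_network":
            value = initial_exponent_network(
                persistence_model(rates, init, steps, A)
            )
            conv = True
        else:
            value, conv = _cell_value(
                quantity, rates, init, steps, A, epsilon, n_max, v
            )
        rows.append(
            {"kappa_w": kw, "kappa_m": 1.0 - kw, "value": value, "converged": conv}
        )
    return pd.DataFrame(rows)


def steps_to_time(n: float, mean_step: float, v: float) -> float:
    """Physical time of n ticks at one segment traversal <l>/v per tick."""
    if mean_step <= 0 or v <= 0:
        raise ParameterError("mean_step and v must be > 0")
    return n * mean_step / v


def time_to_steps(t: float, mean_step: float, v: float) -> float:
    """Number of ticks elapsed in physical time t (inverse of steps_to_time)."""
    if mean_step <= 0 or v <= 0:
        raise ParameterError("mean_step and v must be > 0")
    return t * v / mean_step
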