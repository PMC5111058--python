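"""Occupancy dynamics of the two-state motility chain.

The motion/wait state sequence is a two-state discrete-time Markov chain.
Its occupancy obeys the linear recursion

    q_m(n) = q_m(n-1) (1 - kappa_w) + q_w(n-1) kappa_m,

whose closed-form solution is ``q_m(n) = s + (q_m0 - s) r**n`` with the
relaxation factor ``r = 1 - kappa_w - kappa_m`` and stationary motion
probability ``s = kappa_m / (kappa_m + kappa_w)``.  Residence times in each
state are geometric (the discrete exponential), with mean 1/kappa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Tuple, Union

import numpy as np
import pandas as pd

from .model import FrozenChainError, InitialState, ParameterError, TransitionRates

__all__ = [
    "OccupancySeries",
    "occupancy_evolution",
    "motion_probabilities",
    "stationary_occupancy",
    "residence_time_pmf",
    "mean_residence_time",
    "convergence_step",
]


@dataclass(frozen=True)
class OccupancySeries:
    """State probabilities q_m(n), q_w(n) for n = 0..n_max."""

    steps: np.ndarray
    q_m: np.ndarray

    @property
    def q_w(self) -> np.ndarray:
        return 1.0 - self.q_m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.steps, "q_m": self.q_m, "q_w": self.q_w})


def _qm_closed_form(
    rates: TransitionRates, q_m0: float, n: np.ndarray
) -> np.ndarray:
    if rates.is_frozen:
        return np.full(n.shape, q_m0, dtype=float)
    s = rates.stationary_motion
    r = rates.relaxation
    # integer exponents keep negative r exact and underflow benignly to 0
    return s + (q_m0 - s) * r ** np.asarray(n, dtype=np.int64)


def occupancy_evolution(
    rates: TransitionRates, init: InitialState, n_max: int
) -> OccupancySeries:
    """Closed-form occupancy q_m(n) for n = 0..n_max.

    Identical (to rounding) to iterating the transition kernel directly.
    """
    if n_max < 1:
        raise ParameterError(f"n_max must be >= 1, got {n_max}")
    n = np.arange(0, n_max + 1)
    return OccupancySeries(steps=n, q_m=_qm_closed_form(rates, init.q_m0, n))


def motion_probabilities(
    rates: TransitionRates, init: InitialState, n_max: int
) -> np.ndarray:
    """P_i = q_m(i) for i = 1..n_max: the probability that step i is a motion
    step.  This is the per-step weight entering both MSD engines (the walker
    takes no step at n = 0; the state of step n follows one kernel
    application from the state at n - 1)."""
    return _qm_closed_form(rates, init.q_m0, np.arange(1, n_max + 1))


def stationary_occupancy(rates: TransitionRates) -> Tuple[float, float]:
    """Stationary probabilities ``(P_m_inf, P_w_inf)``.

    ``P_m_inf = kappa_m / (kappa_m + kappa_w)``; raises
    :class:`FrozenChainError` when both rates vanish.
    """
    s = rates.stationary_motion
    return s, 1.0 - s


def _escape_probability(
    state: Literal["motion", "wait"], rates: TransitionRates
) -> float:
    if state == "motion":
        return rates.kappa_w
    if state == "wait":
        return rates.kappa_m
    raise ParameterError(f"state must be 'motion' or 'wait', got {state!r}")


def residence_time_pmf(
    state: Literal["motion", "wait"],
    rates: TransitionRates,
    t: Union[int, np.ndarray],
) -> Union[float, np.ndarray]:
    """Geometric residence-time law P(T = t) = (1 - kappa)**(t-1) * kappa.

    kappa is the escape probability of the state (kappa_w for motion,
    kappa_m for wait).  With kappa = 0 the state is absorbing and the pmf is
    identically zero for finite t (infinite mean).
    """
    kappa = _escape_probability(state, rates)
    t_arr = np.asarray(t)
    if np.any(t_arr < 1) or not np.issubdtype(t_arr.dtype, np.integer):
        raise ParameterError("t must be integer >= 1")
    out = (1.0 - kappa) ** (t_arr - 1) * kappa
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def mean_residence_time(
    state: Literal["motion", "wait"], rates: TransitionRates
) -> float:
    """Mean residence time 1/kappa in steps (inf for an absorbing state)."""
    kappa = _escape_probability(state, rates)
    return np.inf if kappa == 0.0 else 1.0 / kappa


def convergence_step(
    rates: TransitionRates, init: InitialState, tol: float
) -> int:
    """Smallest n with ``|q_m(n) - P_m_inf| < tol``.

    For kappa_w = 0.1, kappa_m = 0.001 starting surely in motion this is 65
    steps at tol = 1e-3, consistent with relaxation within 100 steps.
    """
    if not tol > 0:
        raise ParameterError("tol must be > 0")
    s = rates.stationary_motion  # raises FrozenChainError when frozen
    gap = abs(init.q_m0 - s)
    if gap < tol:
        return 0
    r = abs(rates.relaxation)
    if r == 0.0:
        return 1
    # geometric decay: gap * r**n < tol
    n = int(np.ceil(np.log(gap / tol) / -np.log(r)))
    # guard the ceiling against floating rounding
    while gap * r**n >= tol:
        n += 1
    while n > 0 and gap * r ** (n - 1) < tol:
        n -= 1
    return n
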