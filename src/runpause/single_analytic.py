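"""Exact MSD for unidirectional run-and-pause motion on a single filament.

The walker moves in a fixed direction: x(n) = sum_{i<=n} sigma_i l_i, where
sigma_i in {0, 1} is the motion indicator of the two-state chain and l_i are
i.i.d. step lengths.  Because the direction never changes, the displacement
correlation between two motion steps is just the probability that both are
motion steps:

    <x^2(n)> = <l^2> sum_i P_i + 2 <l>^2 sum_{i<j} P_i G(j - i),

with P_i = q_m(i) the occupancy and G(k) = s + (1 - s) r**k the
motion -> motion k-step return probability.  The asymptotic motion is
ballistic, MSD -> (s <l>)^2 n^2, the fastest possible propagation being the
never-pausing limit kappa_w = 0.

Step-ordering convention: the state of step n follows one kernel application
from the state at n - 1, and the displacement of step n uses that
post-transition state; no step is taken at n = 0.  Hence a motion start with
kappa_w = 1, kappa_m = 0 never moves, and a waiting start with kappa_w = 0
has P_i = 1 - (1 - kappa_m)**i.
"""

from __future__ import annotations

from typing import Union

import numpy as np

from ._corrsum import msd_from_state_correlations
from .markov import motion_probabilities
from .model import (
    InitialState,
    MSDSeries,
    ParameterError,
    StepLengthModel,
    TransitionRates,
    UndefinedExponentError,
)

__all__ = [
    "msd_single",
    "initial_exponent_single",
    "asymptotic_msd_prefactor_single",
    "waiting_start_msd_continuous",
    "waiting_start_local_exponent",
]


def _return_probabilities(rates: TransitionRates, n_max: int) -> np.ndarray:
    """G(k) = P(motion at step i+k | motion at step i), k = 1..n_max-1."""
    k = np.arange(1, n_max)
    if rates.is_frozen:
        return np.ones(k.shape)
    s = rates.stationary_motion
    return s + (1.0 - s) * rates.relaxation**k


def msd_single(
    rates: TransitionRates,
    init: InitialState,
    steps: StepLengthModel,
    n_max: int,
) -> MSDSeries:
    """Exact ensemble MSD at steps 1..n_max, in O(n_max log n_max)."""
    if n_max < 1:
        raise ParameterError(f"n_max must be >= 1, got {n_max}")
    P = motion_probabilities(rates, init, n_max)
    G = _return_probabilities(rates, n_max)
    msd = msd_from_state_correlations(P, G, steps.mean_step, steps.second_moment)
    return MSDSeries(steps=np.arange(1, n_max + 1), msd=msd)


def initial_exponent_single(
    rates: TransitionRates, init: InitialState, steps: StepLengthModel
) -> float:
    """Initial anomalous exponent ``alpha* = log2(MSD(2) / MSD(1))``.

    The power-law fit through the first two MSD points.  2 for a walker that
    never pauses; above 2 for ensembles injected from the waiting state.
    """
    series = msd_single(rates, init, steps, 2)
    m1, m2 = series.msd
    if m1 <= 0.0:
        raise UndefinedExponentError(
            "MSD(1) = 0 (no walker can move on the first step); "
            "the initial exponent is undefined"
        )
    return float(np.log2(m2 / m1))


def asymptotic_msd_prefactor_single(
    rates: TransitionRates, steps: StepLengthModel
) -> float:
    """Prefactor c of the asymptotic ballistic law MSD(n) -> c n^2.

    c = (s <l>)^2 with s the stationary motion probability; kappa_w = 0
    recovers c = <l>^2.
    """
    s = rates.stationary_motion
    return (s * steps.mean_step) ** 2


def waiting_start_msd_continuous(
    kappa_m_rate: float, v: float, t: Union[float, np.ndarray]
) -> Union[float, np.ndarray]:
    """Continuous-time companion of the all-waiting start with kappa_w = 0.

    Each particle waits an Exp(kappa) time t0 and then moves ballistically at
    speed v, so the ensemble MSD is

        int_0^t kappa e^(-kappa t0) v^2 (t - t0)^2 dt0
            = v^2 [t^2 - 2 t / kappa - 2 expm1(-kappa t) / kappa^2].

    The small-t expansion starts at (v^2 kappa / 3) t^3 — an initial
    anomalous exponent of 3, produced purely by the gradual injection of
    particles into the ballistic state — and the large-t behaviour is the
    delayed-ballistic v^2 (t - 1/kappa)^2 + v^2 / kappa^2.

    Evaluated via expm1 so the t^3 regime is computed without catastrophic
    cancellation down to very small t.
    """
    if kappa_m_rate <= 0 or v <= 0:
        raise ParameterError("kappa_m_rate and v must be > 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ParameterError("t must be >= 0")
    k = kappa_m_rate
    out = v**2 * (t_arr**2 - 2.0 * t_arr / k - 2.0 * np.expm1(-k * t_arr) / k**2)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def waiting_start_local_exponent(
    kappa_m_rate: float, v: float, t: float, rel_step: float = 1e-3
) -> float:
    """Local log-log slope d ln MSD / d ln t of the waiting-start closed form,
    by a centred difference; -> 3 as t -> 0 and -> 2 as t -> inf."""
    if t <= 0:
        raise ParameterError("t must be > 0")
    lo = t * (1.0 - rel_step)
    hi = t * (1.0 + rel_step)
    m_lo = waiting_start_msd_continuous(kappa_m_rate, v, lo)
    m_hi = waiting_start_msd_continuous(kappa_m_rate, v, hi)
    return float((np.log(m_hi) - np.log(m_lo)) / (np.log(hi) - np.log(lo)))
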