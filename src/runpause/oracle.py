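"""Brute-force MSD by enumeration over all 2**n motion/wait sequences.

The trust anchor for both analytic engines: every state sequence is
enumerated with its exact chain probability (same step-ordering convention —
the state of step i follows one kernel application from the state at i - 1,
with the initial state marginalized over (q_m0, 1 - q_m0)), and the MSD
contributions are summed term by term.  Exponential in n, capped hard;
clarity over speed.
"""

from __future__ import annotations

import numpy as np

from .model import (
    InitialState,
    NetworkMotilityModel,
    ParameterError,
    StepLengthModel,
    TransitionRates,
)

__all__ = ["enumerate_msd_single", "enumerate_msd_network", "MAX_N_SINGLE", "MAX_N_NETWORK"]

MAX_N_SINGLE = 16
MAX_N_NETWORK = 14

_PROB_SUM_TOL = 1e-12


def _sequence_probabilities(
    rates: TransitionRates, init: InitialState, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """All 2**n state sequences (rows; 1 = motion) and their probabilities."""
    kw, km = rates.kappa_w, rates.kappa_m
    bits = (
        (np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1
    ).astype(np.int8)
    # transition factor from prev state to next state
    def step_prob(prev: np.ndarray, nxt: np.ndarray) -> np.ndarray:
        from_motion = np.where(nxt == 1, 1.0 - kw, kw)
        from_wait = np.where(nxt == 1, km, 1.0 - km)
        return np.where(prev == 1, from_motion, from_wait)

    # marginalize over the (unstepped) initial state
    prob = init.q_m0 * step_prob(np.ones(2**n, dtype=np.int8), bits[:, 0])
    prob += init.q_w0 * step_prob(np.zeros(2**n, dtype=np.int8), bits[:, 0])
    for i in range(1, n):
        prob *= step_prob(bits[:, i - 1], bits[:, i])
    total = prob.sum()
    if abs(total - 1.0) > _PROB_SUM_TOL:
        raise AssertionError(f"sequence probabilities sum to {total!r}, not 1")
    return bits, prob


def enumerate_msd_single(
    rates: TransitionRates, init: InitialState, steps: StepLengthModel, n: int
) -> float:
    """Exact MSD(n) on a single filament by 2**n enumeration (n <= 16).

    Per sequence with m motion steps the contribution is
    <l^2> m + <l>^2 m (m - 1): every ordered pair of distinct motion steps
    contributes <l>^2 since the direction is fixed.
    """
    if not 1 <= n <= MAX_N_SINGLE:
        raise ParameterError(f"n must be in [1, {MAX_N_SINGLE}] for enumeration")
    bits, prob = _sequence_probabilities(rates, init, n)
    m = bits.sum(axis=1).astype(float)
    contrib = steps.second_moment * m + steps.mean_step**2 * m * (m - 1.0)
    return float(np.dot(prob, contrib))


def enumerate_msd_network(model: NetworkMotilityModel, n: int) -> float:
    """Exact MSD(n) on a network by 2**n enumeration (n <= 14).

    A pair of motion steps i < j contributes <l>^2 * A**(number of motion
    steps in (i, j]): the direction update at each moving step in between
    (including j itself) retains a factor A of correlation, waits none.
    """
    if not 1 <= n <= MAX_N_NETWORK:
        raise ParameterError(f"n must be in [1, {MAX_N_NETWORK}] for enumeration")
    A = model.persistence
    bits, prob = _sequence_probabilities(model.rates, model.init, n)
    m_cum = np.cumsum(bits, axis=1)  # motion steps among 1..i
    m = m_cum[:, -1].astype(float)
    cross = np.zeros(bits.shape[0])
    for i in range(n - 1):
        for j in range(i + 1, n):
            both = (bits[:, i] == 1) & (bits[:, j] == 1)
            if not both.any():
                continue
            expo = (m_cum[both, j] - m_cum[both, i]).astype(np.int64)
            cross[both] += np.float_power(A, expo) if A >= 0 else A ** expo
    contrib = (
        model.steps.second_moment * m
        + 2.0 * model.steps.mean_step**2 * cross
    )
    return float(np.dot(prob, contrib))
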