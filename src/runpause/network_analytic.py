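"""Exact MSD and asymptotic transport for the 2D persistent walk on a
coarse-grained filament network.

At each motion step the walker first updates its direction (kept with
probability p, otherwise rotated by a symmetric turn angle, for a mean
retained correlation A = p + (1 - p) E[cos phi]) and then advances by an
i.i.d. segment length; waits leave the direction untouched (the motor sits
at a junction on the same filament).  With an isotropic initial direction,

    <r^2(n)> = <l^2> sum_i P_i + 2 <l>^2 sum_{i<j} P_i g(j - i),

where g(k) is the motion component of M^k applied to the unit motion vector,
with the persistence-weighted transfer matrix

    M = [[A (1 - kappa_w), A kappa_m],
         [kappa_w,         1 - kappa_m]] :

every intervening motion step in (i, j] contributes one factor A to the
direction correlation, while waits only propagate the state.  A = 1 removes
all decorrelation and reduces exactly to the single-filament engine.

For A < 1 the long-time motion is diffusive: MSD(n)/n -> s <l>^2 Gamma with
Gamma(lambda, A) = lambda + 2A / (1 - A), giving the asymptotic diffusion
constant D_inf = s v <l> Gamma / 4 (2D), independent of the initial state.
"""

from __future__ import annotations

import numpy as np

from ._corrsum import msd_from_state_correlations
from .markov import motion_probabilities
from .model import (
    BallisticDivergenceError,
    MSDSeries,
    NetworkMotilityModel,
    ParameterError,
    TransitionRates,
    UndefinedExponentError,
)

__all__ = [
    "msd_network",
    "initial_exponent_network",
    "asymptotic_diffusion",
    "asymptotic_msd_slope",
    "gamma_scale",
]

_EIG_DEGENERACY_TOL = 1e-8


def _direction_correlations(rates: TransitionRates, A: float, n_max: int) -> np.ndarray:
    """g(k) = (M^k e_m)_motion for k = 1..n_max-1.

    Generic case via eigendecomposition of the 2x2 transfer matrix (complex
    pairs are handled and the result is real by symmetry); near-degenerate
    spectra fall back to direct iteration.
    """
    if n_max <= 1:
        return np.zeros(0)
    kw, km = rates.kappa_w, rates.kappa_m
    M = np.array([[A * (1.0 - kw), A * km], [kw, 1.0 - km]])
    k = np.arange(1, n_max)
    mu, V = np.linalg.eig(M)
    scale = max(1.0, float(np.abs(mu).max()))
    if abs(mu[0] - mu[1]) > _EIG_DEGENERACY_TOL * scale:
        w = np.linalg.solve(V, np.array([1.0, 0.0], dtype=V.dtype))
        coef = V[0, :] * w
        g = coef[0] * mu[0] ** k + coef[1] * mu[1] ** k
        return np.ascontiguousarray(g.real)
    # (near-)degenerate spectrum: iterate the recurrence exactly
    g = np.empty(n_max - 1)
    u = np.array([1.0, 0.0])
    for i in range(n_max - 1):
        u = M @ u
        g[i] = u[0]
    return g


def msd_network(model: NetworkMotilityModel, n_max: int) -> MSDSeries:
    """Exact ensemble MSD at steps 1..n_max for the network walk."""
    if n_max < 1:
        raise ParameterError(f"n_max must be >= 1, got {n_max}")
    P = motion_probabilities(model.rates, model.init, n_max)
    g = _direction_correlations(model.rates, model.persistence, n_max)
    msd = msd_from_state_correlations(
        P, g, model.steps.mean_step, model.steps.second_moment
    )
    return MSDSeries(steps=np.arange(1, n_max + 1), msd=msd)


def initial_exponent_network(model: NetworkMotilityModel) -> float:
    """Initial exponent ``alpha* = log2(MSD(2) / MSD(1))``.

    In the single-state case (kappa_w = 0, kappa_m = 1) this reduces to
    log2(2 + 2A / lambda): 1 for non-processive motion on an isotropic
    network, 2 in the ballistic limit A = 1 (constant step).
    """
    series = msd_network(model, 2)
    m1, m2 = series.msd
    if m1 <= 0.0:
        raise UndefinedExponentError(
            "MSD(1) = 0; the initial exponent is undefined"
        )
    return float(np.log2(m2 / m1))


def gamma_scale(lambda_het: float, A: float) -> float:
    """Scale factor Gamma(lambda, A) = lambda + 2A / (1 - A) of the
    asymptotic diffusion law.

    lambda is the dimensionless second moment of the segment lengths; the
    2A/(1-A) term is the summed geometric direction correlation (each pair of
    motion steps k apart contributes A**k, and the sum over k is A/(1-A)
    independently of the switching rates).  Diverges as A -> 1.
    """
    if lambda_het < 1.0:
        raise ParameterError(f"lambda_het must be >= 1, got {lambda_het}")
    if A >= 1.0:
        raise BallisticDivergenceError("Gamma diverges at A = 1 (ballistic limit)")
    if A < -1.0:
        raise ParameterError(f"A must lie in [-1, 1), got {A}")
    return lambda_het + 2.0 * A / (1.0 - A)


def asymptotic_msd_slope(model: NetworkMotilityModel) -> float:
    """Long-time slope of the MSD per step: MSD(n)/n -> s <l>^2 Gamma."""
    s = model.rates.stationary_motion
    return s * model.steps.mean_step**2 * gamma_scale(model.lambda_het, model.persistence)


def asymptotic_diffusion(model: NetworkMotilityModel, v: float) -> float:
    """Asymptotic diffusion constant D_inf = s v <l> Gamma(lambda, A) / 4.

    v is the average motor speed, so v/<l> converts steps to physical time
    and the factor 4 is the 2D MSD normalization (MSD = 4 D t).  Independent
    of the initial motion probability.  Raises for A = 1 (ballistic, D
    diverges) and for a frozen chain.
    """
    if v <= 0:
        raise ParameterError("v must be > 0")
    if model.persistence >= 1.0:
        raise BallisticDivergenceError(
            "A = 1: asymptotically ballistic motion, D_inf diverges"
        )
    s = model.rates.stationary_motion
    return (
        s
        * v
        * model.steps.mean_step
        * gamma_scale(model.lambda_het, model.persistence)
        / 4.0
    )
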