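"""Domain types for two-state run-and-pause motility models.

A motor protein on a cytoskeletal filament alternates between an active
*motion* state, in which it translocates, and a *pause* (waiting) state, in
which it stays put.  Switching is Markovian: per discrete time step the motor
leaves the motion state with probability ``kappa_w`` and leaves the waiting
state with probability ``kappa_m``.  On a filament network the moving motor
additionally either continues along its current filament (processivity ``p``)
or hops onto an intersecting one, turning by an angle drawn from a symmetric
distribution ``R(phi)``.  Segment lengths between junctions are i.i.d. draws
from a step-length distribution ``f(l)``.

Only three reduced parameters of the environment enter the displacement
moments:

* the heterogeneity ``lambda_het = <l^2>/<l>^2`` of the segment lengths
  (1 for a constant step),
* the anisotropy ``r_hat = E[cos phi]`` of the turn-angle distribution
  (0 for an isotropic network, -> 1 for aligned filaments),
* the effective persistence ``A = p + (1 - p) * r_hat``, the directional
  correlation retained per motion step.

All lengths are dimensionless model units; physical units enter only through
the conversions in :mod:`runpause.phase`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParameterError",
    "FrozenChainError",
    "UndefinedExponentError",
    "BallisticDivergenceError",
    "TransitionRates",
    "InitialState",
    "StepLengthModel",
    "TurnAngleModel",
    "NetworkMotilityModel",
    "MSDSeries",
    "ExponentSeries",
    "CrossoverResult",
    "PhaseGrid",
    "constant_steps",
    "exponential_steps",
    "custom_steps",
    "uniform_turns",
    "delta_turns",
    "discrete_turns",
    "wrapped_normal_turns",
    "turns_from_anisotropy",
    "make_network_model",
    "persistence_model",
]

Sampler = Callable[[np.random.Generator, int], np.ndarray]


class ParameterError(ValueError):
    """A model parameter is outside its admissible range."""


class FrozenChainError(ParameterError):
    """kappa_w = kappa_m = 0: the state never changes, no stationary law."""


class UndefinedExponentError(ValueError):
    """MSD(1) = 0, so no power law can be fitted to the first two points."""


class BallisticDivergenceError(ParameterError):
    """A = 1: directional memory never decays, the walk stays ballistic and
    the asymptotic diffusion constant diverges."""


def _check_prob(name: str, value: float) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0) or math.isnan(value):
        raise ParameterError(f"{name} must lie in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class TransitionRates:
    """Per-step switching probabilities of the two-state motility chain.

    Parameters
    ----------
    kappa_w : float
        Probability of switching motion -> wait in one step.
    kappa_m : float
        Probability of switching wait -> motion in one step.
    """

    kappa_w: float
    kappa_m: float

    def __post_init__(self) -> None:
        _check_prob("kappa_w", self.kappa_w)
        _check_prob("kappa_m", self.kappa_m)

    @property
    def relaxation(self) -> float:
        """Relaxation factor ``r = 1 - kappa_w - kappa_m`` of the occupancy
        recursion; |r| <= 1 always, and q_m(n) - s decays like r**n."""
        return 1.0 - self.kappa_w - self.kappa_m

    @property
    def is_frozen(self) -> bool:
        return self.kappa_w == 0.0 and self.kappa_m == 0.0

    @property
    def stationary_motion(self) -> float:
        """Stationary motion-state probability ``s = kappa_m / (kappa_m + kappa_w)``."""
        if self.is_frozen:
            raise FrozenChainError(
                "kappa_w = kappa_m = 0 has no stationary distribution"
            )
        return self.kappa_m / (self.kappa_m + self.kappa_w)


@dataclass(frozen=True)
class InitialState:
    """Probability ``q_m0`` of starting in the motion state."""

    q_m0: float

    def __post_init__(self) -> None:
        _check_prob("q_m0", self.q_m0)

    @property
    def q_w0(self) -> float:
        return 1.0 - self.q_m0


@dataclass(frozen=True)
class StepLengthModel:
    """Moments (and optionally a sampler) of the step-length distribution.

    Only the first two moments enter the exact MSD; the sampler is needed for
    Monte Carlo simulation only.

    Attributes
    ----------
    mean_step : float
        ``<l> > 0``.
    second_moment : float
        ``<l^2> >= <l>^2``.
    sampler : callable, optional
        ``sampler(rng, size) -> ndarray`` drawing i.i.d. step lengths.
    """

    mean_step: float
    second_moment: float
    sampler: Optional[Sampler] = field(default=None, compare=False)
    name: str = "custom"

    def __post_init__(self) -> None:
        if not self.mean_step > 0:
            raise ParameterError(f"mean_step must be > 0, got {self.mean_step!r}")
        if self.second_moment < self.mean_step**2 * (1 - 1e-12):
            raise ParameterError(
                "second_moment must be >= mean_step**2 "
                f"(got {self.second_moment!r} < {self.mean_step**2!r})"
            )

    @property
    def lambda_het(self) -> float:
        """Heterogeneity ``lambda = <l^2> / <l>^2`` (>= 1; 1 iff constant)."""
        return self.second_moment / self.mean_step**2


def constant_steps(length: float = 1.0) -> StepLengthModel:
    """Constant step length (lambda = 1), the single-filament default."""
    return StepLengthModel(
        mean_step=length,
        second_moment=length**2,
        sampler=lambda rng, size: np.full(size, float(length)),
        name=f"constant({length})",
    )


def exponential_steps(mean: float = 1.0) -> StepLengthModel:
    """Exponentially distributed segment lengths (lambda = 2), a common model
    for the spacing of junctions on disordered networks."""
    return StepLengthModel(
        mean_step=mean,
        second_moment=2.0 * mean**2,
        sampler=lambda rng, size: rng.exponential(mean, size),
        name=f"exponential({mean})",
    )


def custom_steps(
    mean_step: float,
    second_moment: float,
    sampler: Optional[Sampler] = None,
) -> StepLengthModel:
    """Step-length model given directly by its first two moments."""
    return StepLengthModel(mean_step, second_moment, sampler)


@dataclass(frozen=True)
class TurnAngleModel:
    """Turn-angle distribution ``R(phi)`` on (-pi, pi], reduced to its mean
    cosine.  R must be symmetric about 0 (``E[sin phi] = 0``); the moment
    algebra for the network MSD relies on it, so asymmetric samplers are
    rejected at model-construction time.
    """

    r_hat: float
    sampler: Optional[Sampler] = field(default=None, compare=False)
    name: str = "custom"

    def __post_init__(self) -> None:
        if not (-1.0 <= self.r_hat <= 1.0) or math.isnan(self.r_hat):
            raise ParameterError(f"r_hat must lie in [-1, 1], got {self.r_hat!r}")


def uniform_turns() -> TurnAngleModel:
    """Isotropic turning (r_hat = 0), e.g. a random actin mesh."""
    return TurnAngleModel(
        r_hat=0.0,
        sampler=lambda rng, size: rng.uniform(-np.pi, np.pi, size),
        name="uniform",
    )


def delta_turns(angle: float = 0.0) -> TurnAngleModel:
    """All turns equal to ``angle``; only 0 and pi are symmetric."""
    a = float(angle)
    if not (math.isclose(abs(a), 0.0, abs_tol=1e-12) or math.isclose(abs(a), math.pi)):
        raise ParameterError("delta turn distribution is symmetric only at 0 or pi")
    return TurnAngleModel(
        r_hat=math.cos(a),
        sampler=lambda rng, size: np.full(size, a),
        name=f"delta({a})",
    )


def discrete_turns(
    angles: Sequence[float], weights: Optional[Sequence[float]] = None
) -> TurnAngleModel:
    """Discrete symmetric turn distribution.

    Every angle's weight must equal the weight of its mirror image -phi
    (modulo 2*pi).  ``discrete_turns([0, np.pi/2, -np.pi/2])`` is the
    square-lattice junction rule (continue, turn left, turn right, no
    reversal), with mean cosine 1/3.
    """
    ang = np.asarray(angles, dtype=float)
    w = (
        np.full(ang.size, 1.0 / ang.size)
        if weights is None
        else np.asarray(weights, dtype=float)
    )
    if w.shape != ang.shape:
        raise ParameterError("angles and weights must have equal length")
    if np.any(w < 0) or not math.isclose(w.sum(), 1.0, rel_tol=1e-9):
        raise ParameterError("weights must be non-negative and sum to 1")
    # symmetry: total weight at phi must equal total weight at -phi
    wrapped = np.mod(ang + np.pi, 2 * np.pi) - np.pi
    for a in wrapped:
        w_pos = w[np.isclose(wrapped, a)].sum()
        w_neg = w[np.isclose(wrapped, -a) | np.isclose(wrapped, 2 * np.pi - a)].sum()
        if not math.isclose(w_pos, w_neg, rel_tol=1e-9, abs_tol=1e-12):
            raise ParameterError(
                f"turn distribution not symmetric: weight({a:+.4f}) = {w_pos} "
                f"but weight({-a:+.4f}) = {w_neg}"
            )
    r_hat = float(np.sum(w * np.cos(ang)))

    def sampler(rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(ang, size=size, p=w)

    return TurnAngleModel(r_hat=r_hat, sampler=sampler, name="discrete")


def wrapped_normal_turns(sigma: float) -> TurnAngleModel:
    """Wrapped-normal turning with angular spread ``sigma``; r_hat = exp(-sigma^2/2)."""
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")

    def sampler(rng: np.random.Generator, size: int) -> np.ndarray:
        raw = rng.normal(0.0, sigma, size)
        return np.mod(raw + np.pi, 2 * np.pi) - np.pi

    return TurnAngleModel(
        r_hat=math.exp(-0.5 * sigma**2), sampler=sampler, name=f"wrapped_normal({sigma})"
    )


def turns_from_anisotropy(r_hat: float) -> TurnAngleModel:
    """A symmetric turn model with the requested mean cosine.

    Uses the uniform distribution for r_hat = 0, a forward delta for
    r_hat = 1, and a wrapped normal (sigma = sqrt(-2 ln r_hat)) in between.
    Negative anisotropies have no canonical one-parameter family here; build
    one explicitly with :func:`discrete_turns`.
    """
    if r_hat == 0.0:
        return uniform_turns()
    if r_hat == 1.0:
        return delta_turns(0.0)
    if not 0.0 < r_hat < 1.0:
        raise ParameterError(
            "turns_from_anisotropy covers 0 <= r_hat <= 1; "
            "use discrete_turns for negative anisotropy"
        )
    return wrapped_normal_turns(math.sqrt(-2.0 * math.log(r_hat)))


# number of draws used to screen a sampler for asymmetry at construction time
_SYMMETRY_DRAWS = 20000
_SYMMETRY_SEED = 1234


@dataclass(frozen=True)
class NetworkMotilityModel:
    """Full parameter set for run-and-pause motion on a filament network."""

    rates: TransitionRates
    init: InitialState
    steps: StepLengthModel
    turns: TurnAngleModel
    processivity: float = 0.0

    def __post_init__(self) -> None:
        _check_prob("processivity", self.processivity)

    @property
    def persistence(self) -> float:
        """Effective persistence ``A = p + (1 - p) * r_hat`` in [-1, 1]."""
        p = self.processivity
        return p + (1.0 - p) * self.turns.r_hat

    @property
    def lambda_het(self) -> float:
        return self.steps.lambda_het


def make_network_model(
    rates: TransitionRates,
    init: InitialState,
    steps: StepLengthModel,
    turns: TurnAngleModel,
    p: float = 0.0,
) -> NetworkMotilityModel:
    """Validate components and assemble a :class:`NetworkMotilityModel`.

    If the turn model carries a sampler, it is screened numerically for
    symmetry: a detectably nonzero ``E[sin phi]`` is rejected rather than
    silently projected out, because the MSD algebra assumes it vanishes.
    """
    model = NetworkMotilityModel(rates, init, steps, turns, p)
    if turns.sampler is not None:
        rng = np.random.Generator(np.random.Philox(_SYMMETRY_SEED))
        draws = np.asarray(turns.sampler(rng, _SYMMETRY_DRAWS), dtype=float)
        mean_sin = float(np.mean(np.sin(draws)))
        # mean of sin has sd <= sqrt(1/2 N); 5 sigma of the worst case
        if abs(mean_sin) > 5.0 * math.sqrt(0.5 / _SYMMETRY_DRAWS):
            raise ParameterError(
                f"turn-angle sampler looks asymmetric: E[sin phi] ~= {mean_sin:.4f}"
            )
    return model


def persistence_model(
    rates: TransitionRates,
    init: InitialState,
    steps: StepLengthModel,
    A: float,
) -> NetworkMotilityModel:
    """Network model specified directly by its effective persistence A >= 0
    (p = 0 and a symmetric turn model with mean cosine A)."""
    return make_network_model(rates, init, steps, turns_from_anisotropy(A), p=0.0)


# ---------------------------------------------------------------------------
# series / result containers


@dataclass(frozen=True)
class MSDSeries:
    """Mean squared displacement about the origin at integer steps."""

    steps: np.ndarray
    msd: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", np.asarray(self.steps, dtype=np.int64))
        object.__setattr__(self, "msd", np.asarray(self.msd, dtype=float))
        if self.steps.shape != self.msd.shape:
            raise ValueError("steps and msd must have equal shape")

    def __len__(self) -> int:
        return self.steps.size

    def value_at(self, n: int) -> float:
        idx = np.searchsorted(self.steps, n)
        if idx >= self.steps.size or self.steps[idx] != n:
            raise KeyError(f"step {n} not in series")
        return float(self.msd[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.steps, "msd": self.msd})


@dataclass(frozen=True)
class ExponentSeries:
    """Running anomalous exponent alpha(n), the local log-log MSD slope."""

    steps: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", np.asarray(self.steps, dtype=np.int64))
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))

    def __len__(self) -> int:
        return self.steps.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.steps, "alpha": self.alpha})


@dataclass(frozen=True)
class CrossoverResult:
    """Step at which alpha settles within epsilon of its asymptote."""

    n_c: int
    epsilon: float
    target_exponent: float
    converged: bool


@dataclass(frozen=True)
class PhaseGrid:
    """A scanned quantity on a (kappa_w, kappa_m) grid.

    ``matrix[i, j]`` corresponds to ``kappa_w_values[i]``,
    ``kappa_m_values[j]``.  For crossover scans, ``converged[i, j]`` is False
    where the crossover was not reached within the horizon; such cells hold
    the horizon as a lower bound and must not be interpolated.
    """

    kappa_w_values: np.ndarray
    kappa_m_values: np.ndarray
    matrix: np.ndarray
    quantity: str
    converged: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        kw = np.asarray(self.kappa_w_values, dtype=float)
        km = np.asarray(self.kappa_m_values, dtype=float)
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (kw.size, km.size):
            raise ValueError(
                f"matrix shape {m.shape} != ({kw.size}, {km.size})"
            )
        object.__setattr__(self, "kappa_w_values", kw)
        object.__setattr__(self, "kappa_m_values", km)
        object.__setattr__(self, "matrix", m)

    def to_frame(self) -> pd.DataFrame:
        kw, km = np.meshgrid(self.kappa_w_values, self.kappa_m_values, indexing="ij")
        data = {
            "kappa_w": kw.ravel(),
            "kappa_m": km.ravel(),
            "value": self.matrix.ravel(),
        }
        if self.converged is not None:
            data["converged"] = np.asarray(self.converged).ravel()
        return pd.DataFrame(data)
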