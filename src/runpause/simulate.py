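"""Seeded Monte Carlo ensembles for both model variants.

Walkers are simulated in fixed-size chunks of 16384; each chunk gets its own
Philox stream spawned from the master seed, so results are bit-reproducible
regardless of execution order, and the first N walkers are unchanged when
the ensemble is enlarged.  The MSD standard error is estimated from the
ensemble variance of the squared displacement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd

from .model import (
    InitialState,
    NetworkMotilityModel,
    ParameterError,
    StepLengthModel,
    TransitionRates,
)

__all__ = [
    "EnsembleResult",
    "simulate_single",
    "simulate_network",
    "sample_residence_times",
    "record_grid",
]

_CHUNK = 16384


@dataclass(frozen=True)
class EnsembleResult:
    """Ensemble-averaged MSD with standard errors at recorded steps."""

    steps: np.ndarray
    msd: np.ndarray
    stderr: np.ndarray
    n_walkers: int
    seed: int
    motion_fraction: Optional[np.ndarray] = None
    final_positions: Optional[np.ndarray] = field(default=None, compare=False)

    def to_frame(self) -> pd.DataFrame:
        data = {"n": self.steps, "msd": self.msd, "stderr": self.stderr}
        if self.motion_fraction is not None:
            data["motion_fraction"] = self.motion_fraction
        return pd.DataFrame(data)


def record_grid(
    n_steps: int, record: Union[str, np.ndarray] = "log", points: int = 64
) -> np.ndarray:
    """Recording steps: every step ("all"), a log-spaced grid ("log"), or an
    explicit sorted array of steps in [1, n_steps]."""
    if isinstance(record, str):
        if record == "all":
            return np.arange(1, n_steps + 1)
        if record == "log":
            grid = np.unique(
                np.round(np.logspace(0.0, math.log10(n_steps), points)).astype(np.int64)
            )
            return grid[(grid >= 1) & (grid <= n_steps)]
        raise ParameterError(f"record must be 'all', 'log' or an array, got {record!r}")
    grid = np.asarray(record, dtype=np.int64)
    if grid.size == 0 or grid.min() < 1 or grid.max() > n_steps or np.any(np.diff(grid) <= 0):
        raise ParameterError("recording steps must be sorted, unique, within [1, n_steps]")
    return grid


def _chunk_streams(seed: int, n_walkers: int):
    n_chunks = (n_walkers + _CHUNK - 1) // _CHUNK
    children = np.random.SeedSequence(seed).spawn(n_chunks)
    for idx, child in enumerate(children):
        size = min(_CHUNK, n_walkers - idx * _CHUNK)
        yield np.random.Generator(np.random.Philox(child)), size


def _validate_sizes(n_steps: int, n_walkers: int, seed: int) -> None:
    if n_steps < 1 or n_walkers < 1:
        raise ParameterError("n_steps and n_walkers must be >= 1")
    if not isinstance(seed, (int, np.integer)) or seed < 0:
        raise ParameterError("seed must be a non-negative integer")


def _advance_state(
    rng: np.random.Generator, state: np.ndarray, kw: float, km: float
) -> np.ndarray:
    u = rng.random(state.size)
    return np.where(state, u >= kw, u < km)


def simulate_single(
    rates: TransitionRates,
    init: InitialState,
    steps: StepLengthModel,
    n_steps: int,
    n_walkers: int,
    seed: int,
    record: Union[str, np.ndarray] = "log",
    keep_final: bool = False,
) -> EnsembleResult:
    """Monte Carlo ensemble for unidirectional run-and-pause motion.

    Each walker starts in motion with probability q_m0, applies the
    transition kernel once per step, and advances by a sampled step length
    whenever it is in the motion state (fixed positive direction).
    """
    _validate_sizes(n_steps, n_walkers, seed)
    if steps.sampler is None:
        raise ParameterError("step-length model has no sampler; simulation needs one")
    rec = record_grid(n_steps, record)
    sum_sq = np.zeros(rec.size)
    sum_q = np.zeros(rec.size)
    motion_ct = np.zeros(rec.size)
    finals = [] if keep_final else None
    kw, km = rates.kappa_w, rates.kappa_m
    for rng, size in _chunk_streams(seed, n_walkers):
        state = rng.random(size) < init.q_m0
        x = np.zeros(size)
        ri = 0
        for n in range(1, n_steps + 1):
            state = _advance_state(rng, state, kw, km)
            ell = np.asarray(steps.sampler(rng, size), dtype=float)
            x += ell * state
            if ri < rec.size and n == rec[ri]:
                sq = x * x
                sum_sq[ri] += sq.sum()
                sum_q[ri] += (sq * sq).sum()
                motion_ct[ri] += state.sum()
                ri += 1
        if keep_final:
            finals.append(x.copy())
    msd = sum_sq / n_walkers
    var = np.maximum(sum_q / n_walkers - msd**2, 0.0)
    stderr = np.sqrt(var / n_walkers)
    return EnsembleResult(
        steps=rec,
        msd=msd,
        stderr=stderr,
        n_walkers=n_walkers,
        seed=int(seed),
        motion_fraction=motion_ct / n_walkers,
        final_positions=np.concatenate(finals) if keep_final else None,
    )


def simulate_network(
    model: NetworkMotilityModel,
    n_steps: int,
    n_walkers: int,
    seed: int,
    record: Union[str, np.ndarray] = "log",
    keep_final: bool = False,
) -> EnsembleResult:
    """Monte Carlo ensemble for the 2D persistent network walk.

    Initial direction uniform on (-pi, pi]; at each motion step the walker
    keeps its direction with probability p, otherwise turns by a draw from
    R(phi), then advances by a sampled segment length.  Waits preserve the
    direction.
    """
    _validate_sizes(n_steps, n_walkers, seed)
    if model.steps.sampler is None or model.turns.sampler is None:
        raise ParameterError("simulation needs both step-length and turn samplers")
    rec = record_grid(n_steps, record)
    sum_sq = np.zeros(rec.size)
    sum_q = np.zeros(rec.size)
    motion_ct = np.zeros(rec.size)
    finals = [] if keep_final else None
    rates, init = model.rates, model.init
    kw, km = rates.kappa_w, rates.kappa_m
    p = model.processivity
    for rng, size in _chunk_streams(seed, n_walkers):
        state = rng.random(size) < init.q_m0
        theta = rng.uniform(-np.pi, np.pi, size)
        x = np.zeros(size)
        y = np.zeros(size)
        ri = 0
        for n in range(1, n_steps + 1):
            state = _advance_state(rng, state, kw, km)
            keep = rng.random(size) < p
            dphi = np.asarray(model.turns.sampler(rng, size), dtype=float)
            theta = theta + np.where(state & ~keep, dphi, 0.0)
            ell = np.asarray(model.steps.sampler(rng, size), dtype=float)
            x += ell * state * np.cos(theta)
            y += ell * state * np.sin(theta)
            if ri < rec.size and n == rec[ri]:
                sq = x * x + y * y
                sum_sq[ri] += sq.sum()
                sum_q[ri] += (sq * sq).sum()
                motion_ct[ri] += state.sum()
                ri += 1
        if keep_final:
            finals.append(np.column_stack([x, y]))
    msd = sum_sq / n_walkers
    var = np.maximum(sum_q / n_walkers - msd**2, 0.0)
    stderr = np.sqrt(var / n_walkers)
    return EnsembleResult(
        steps=rec,
        msd=msd,
        stderr=stderr,
        n_walkers=n_walkers,
        seed=int(seed),
        motion_fraction=motion_ct / n_walkers,
        final_positions=np.concatenate(finals) if keep_final else None,
    )


def sample_residence_times(
    state: Literal["motion", "wait"],
    rates: TransitionRates,
    n_samples: int,
    seed: int,
    t_cap: int = 10_000,
) -> np.ndarray:
    """Residence times sampled by running the per-step escape mechanics.

    Each sample repeatedly draws the per-step uniform against the escape
    probability kappa until the state is left, mirroring exactly what the
    ensemble simulators do; capped at ``t_cap`` steps (censored samples are
    returned at the cap).
    """
    if state == "motion":
        kappa = rates.kappa_w
    elif state == "wait":
        kappa = rates.kappa_m
    else:
        raise ParameterError(f"state must be 'motion' or 'wait', got {state!r}")
    if kappa == 0.0:
        raise ParameterError("absorbing state: residence time is infinite")
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    times = np.full(n_samples, t_cap, dtype=np.int64)
    alive = np.arange(n_samples)
    for t in range(1, t_cap + 1):
        if alive.size == 0:
            break
        escaped = rng.random(alive.size) < kappa
        times[alive[escaped]] = t
        alive = alive[~escaped]
    return times
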