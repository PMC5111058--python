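"""Running anomalous exponent, crossover detection and regime labels.

alpha(n) is the local slope of the MSD in log-log coordinates, fitted to
successive steps n and n+1.  The crossover step n_c to an asymptotic
exponent (2 on a single filament, 1 on a network) is the step after the last
violation of |alpha - target| < epsilon within the computed horizon — a
*sustained* criterion, robust to transient overshoots such as the
super-ballistic excursions of waiting-start ensembles.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from .model import CrossoverResult, ExponentSeries, MSDSeries, ParameterError

__all__ = [
    "alpha_series",
    "crossover_time",
    "classify_regimes",
    "DEFAULT_EPSILON",
]

#: threshold on |alpha - target| used for crossover detection by default
DEFAULT_EPSILON = 1e-2


def alpha_series(msd: MSDSeries) -> ExponentSeries:
    """alpha(n) = [ln MSD(n+1) - ln MSD(n)] / [ln(n+1) - ln n].

    Requires the series on consecutive integers with positive values.
    """
    n = msd.steps
    if n.size < 2:
        raise ParameterError("need at least two MSD points")
    if np.any(np.diff(n) != 1):
        raise ParameterError("MSD series must be on consecutive integer steps")
    if np.any(msd.msd <= 0.0):
        raise ParameterError("alpha is undefined where MSD <= 0")
    ln_m = np.log(msd.msd)
    ln_n = np.log(n.astype(float))
    alpha = np.diff(ln_m) / np.diff(ln_n)
    return ExponentSeries(steps=n[:-1], alpha=alpha)


def crossover_time(
    alpha: ExponentSeries, target: float, epsilon: float = DEFAULT_EPSILON
) -> CrossoverResult:
    """Sustained crossover step to |alpha - target| < epsilon.

    n_c = 1 + (last step with a violation); 1 if the exponent is within the
    band everywhere.  ``converged`` is False when the band is still violated
    at the end of the horizon, in which case n_c is only a lower bound.
    """
    if epsilon <= 0:
        raise ParameterError("epsilon must be > 0")
    if len(alpha) == 0:
        raise ParameterError("empty exponent series")
    delta = np.abs(alpha.alpha - target)
    violations = delta >= epsilon
    if not violations.any():
        return CrossoverResult(
            n_c=1, epsilon=epsilon, target_exponent=target, converged=True
        )
    last_violation = int(alpha.steps[violations][-1])
    converged = not bool(violations[-1])
    return CrossoverResult(
        n_c=last_violation + 1,
        epsilon=epsilon,
        target_exponent=target,
        converged=converged,
    )


_REGIME_LABELS = ("subdiffusive", "diffusive", "superdiffusive", "ballistic", "super-ballistic")


def _label(a: float, tol: float) -> str:
    if a < 1.0 - tol:
        return "subdiffusive"
    if a <= 1.0 + tol:
        return "diffusive"
    if a < 2.0 - tol:
        return "superdiffusive"
    if a <= 2.0 + tol:
        return "ballistic"
    return "super-ballistic"


def classify_regimes(
    alpha: ExponentSeries, tol: float = 0.05
) -> List[Tuple[Tuple[int, int], str]]:
    """Maximal runs of constant diffusion regime.

    Returns ``[((n_start, n_end), label), ...]`` with inclusive step ranges
    and labels among sub/diffusive/super/ballistic/super-ballistic.
    """
    if tol <= 0:
        raise ParameterError("tol must be > 0")
    out: List[Tuple[Tuple[int, int], str]] = []
    if len(alpha) == 0:
        return out
    labels = [_label(a, tol) for a in alpha.alpha]
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append(
                ((int(alpha.steps[start]), int(alpha.steps[i - 1])), labels[start])
            )
            start = i
    return out
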