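"""Shared correlation-sum machinery for the exact MSD engines.

Both the single-filament and the network walk have displacements of the form
``sum_i sigma_i l_i e_i`` with sigma_i the motion indicator, so

    <r^2(n)> = <l^2> * sum_i P_i  +  2 <l>^2 * sum_{i<j} P_i * g(j - i),

where ``P_i`` is the unconditional motion probability of step i and ``g(k)``
the conditional correlation of a step with the step k later (state return
probability, times the retained direction correlation on the network).  The
double sum is a discrete convolution of P with g, evaluated directly for
short horizons and via FFT for long ones.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

# below this horizon np.convolve's exact direct sum is used
_DIRECT_LIMIT = 2048


def cross_term_cumsum(P: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Cumulative double sum T(n) = sum_{j<=n} sum_{i<j} P_i g_{j-i}.

    P has entries P_1..P_n (index 0 <-> i = 1); g has entries g_1..g_{n-1}.
    Returns an array of length n with T(1) = 0 in slot 0.
    """
    n = P.size
    out = np.zeros(n)
    if n == 1:
        return out
    a, b = P[:-1], g
    if n <= _DIRECT_LIMIT:
        conv = np.convolve(a, b)[: n - 1]
    else:
        conv = fftconvolve(a, b)[: n - 1]
    np.cumsum(conv, out=out[1:])
    return out


def msd_from_state_correlations(
    P: np.ndarray, g: np.ndarray, mean_step: float, second_moment: float
) -> np.ndarray:
    """Exact MSD(1..n) from per-step motion probabilities and correlations."""
    diag = second_moment * np.cumsum(P)
    cross = 2.0 * mean_step**2 * cross_term_cumsum(P, g)
    return diag + cross
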