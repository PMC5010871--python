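"""Numba-compiled inner loops for the coordinate-descent fitter.

The three built-in models are evaluated point-wise inside a compiled
loop so that fitting thousands of 13-point curves (a full chip run is
144 peptides x 3 models per sample) stays cheap.  The algorithm here is
identical, decision for decision, to the generic pure-Python engine in
``kinofit.fitter.coordinate_descent``; a test asserts their agreement.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _eval_point(code: int, p: np.ndarray, c: float) -> float:
    if code == 1:  # y0 + ymax*(1 - exp(-k*c))
        return p[0] + p[1] * (1.0 - math.exp(-p[2] * c))
    elif code == 2:  # y0 + ymax*(1 - exp(-k*(c - c0)))
        return p[0] + p[1] * (1.0 - math.exp(-p[2] * (c - p[3])))
    else:  # ymax*vi*(c - c0) / (ymax + vi*(c - c0))
        num = p[1] * (c - p[2])
        den = p[0] + num
        if den == 0.0:
            return np.nan
        return p[0] * num / den


@njit(cache=True)
def _sse(code: int, p: np.ndarray, cycles: np.ndarray, signals: np.ndarray) -> float:
    total = 0.0
    for i in range(cycles.size):
        r = _eval_point(code, p, cycles[i]) - signals[i]
        total += r * r
    return total


@njit(cache=True)
def descend(
    code: int,
    cycles: np.ndarray,
    signals: np.ndarray,
    params: np.ndarray,
    steps: np.ndarray,
    max_iterations: int,
    min_sse_percent_change: float,
    step_growth: float,
    step_reversal: float,
):
    """Coordinate-wise adaptive-step SSE minimization.

    One iteration is a full sweep over the parameters in order.  A
    proposal ``p_j + s_j`` is accepted only on a strict SSE decrease
    (then ``s_j *= step_growth``); otherwise the parameter is restored
    and ``s_j *= step_reversal`` (sign flips, magnitude halves at the
    default -0.5).  Non-finite proposals are rejected.  Stops when the
    percent SSE change over an improving sweep drops below the
    threshold or at the iteration cap; a sweep rejecting every proposal
    only shrinks the steps and the search continues.  Returns
    (params, steps, sse, iterations, converged).
    """
    p = params.copy()
    s = steps.copy()
    sse = _sse(code, p, cycles, signals)
    iterations = 0
    converged = False
    for iterations in range(1, max_iterations + 1):
        sse_prev = sse
        if sse_prev == 0.0:
            converged = True
            iterations -= 1
            break
        for j in range(p.size):
            old = p[j]
            p[j] = old + s[j]
            trial = _sse(code, p, cycles, signals)
            if np.isfinite(trial) and trial < sse:
                sse = trial
                s[j] = s[j] * step_growth
            else:
                p[j] = old
                s[j] = s[j] * step_reversal
        if sse < sse_prev:
            pct = 100.0 * (sse_prev - sse) / sse_prev
            if pct < min_sse_percent_change:
                converged = True
                break
    return p, s, sse, iterations, converged
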