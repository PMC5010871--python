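"""Goodness of fit: R-squared, Wald-Wolfowitz runs test, and the QC gate.

Lack of fit of a kinetic model shows up as long stretches of
same-signed residuals, i.e. too few sign runs.  The runs test used here
is therefore one-sided: the p-value is P(Runs <= R_observed) under the
exact conditional distribution of run counts given the numbers of
positive and negative residuals (used whenever n1 + n2 <= 30, which
covers 13-point curves comfortably), with a continuity-corrected normal
approximation as the large-sample fallback.  A peptide passes quality
control when its runs-test p-value is >= alpha (default 0.05); the
joint gate of the analysis pipeline additionally requires all three
candidate models to pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, erf, sqrt
from typing import NamedTuple

import numpy as np

__all__ = [
    "r_squared",
    "runs_test",
    "runs_test_detail",
    "runs_distribution",
    "RunsTestResult",
    "QCReport",
    "qc_gate",
]

#: largest n1 + n2 for which the exact conditional distribution is used
EXACT_LIMIT = 30


def r_squared(series, fitted) -> float:
    """Coefficient of determination 1 - SSE/SStot (may be negative)."""
    y = np.asarray(series.signals if hasattr(series, "signals") else series, float)
    f = np.asarray(fitted, dtype=float)
    if y.shape != f.shape:
        raise ValueError("observed and fitted vectors differ in length")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("zero-variance series: R^2 undefined")
    ss_err = float(np.sum((y - f) ** 2))
    return 1.0 - ss_err / ss_tot


def runs_distribution(n1: int, n2: int) -> np.ndarray:
    """Exact pmf of the run count given n1 positive and n2 negative signs.

    Index r of the returned vector is P(Runs = r); entries 0 and 1 are
    zero except for the degenerate single-sign cases.  All C(n1+n2, n1)
    orderings are equally likely under the null of random residual signs.
    """
    if n1 < 0 or n2 < 0 or n1 + n2 == 0:
        raise ValueError("need at least one signed residual")
    n = n1 + n2
    pmf = np.zeros(n + 1)
    if n1 == 0 or n2 == 0:
        pmf[1] = 1.0
        return pmf
    total = comb(n, n1)
    for r in range(2, n + 1):
        if r % 2 == 0:
            m = r // 2
            ways = 2 * comb(n1 - 1, m - 1) * comb(n2 - 1, m - 1)
        else:
            m = (r - 1) // 2
            ways = comb(n1 - 1, m - 1) * comb(n2 - 1, m) + comb(
                n1 - 1, m
            ) * comb(n2 - 1, m - 1)
        pmf[r] = ways / total
    return pmf


def _count_runs(signs: np.ndarray) -> int:
    return int(1 + np.sum(signs[1:] != signs[:-1]))


class RunsTestResult(NamedTuple):
    p_value: float
    n_positive: int
    n_negative: int
    runs: int
    degenerate: bool
    exact: bool


def runs_test_detail(residuals) -> RunsTestResult:
    """One-sided (too-few-runs) Wald-Wolfowitz test on residual signs.

    Zero residuals are dropped before counting signs.  If every
    residual is zero the test is degenerate and p = 1 is reported with
    a flag.
    """
    resid = np.asarray(residuals, dtype=float)
    signs = np.sign(resid[resid != 0.0])
    if signs.size == 0:
        return RunsTestResult(1.0, 0, 0, 0, True, True)
    n1 = int(np.sum(signs > 0))
    n2 = int(np.sum(signs < 0))
    runs = _count_runs(signs)
    n = n1 + n2
    if n <= EXACT_LIMIT:
        pmf = runs_distribution(n1, n2)
        p = float(pmf[: runs + 1].sum())
        return RunsTestResult(min(p, 1.0), n1, n2, runs, False, True)
    # normal approximation with continuity correction
    mu = 1.0 + 2.0 * n1 * n2 / n
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n * n * (n - 1.0))
    if var <= 0.0:
        return RunsTestResult(1.0, n1, n2, runs, True, False)
    z = (runs + 0.5 - mu) / sqrt(var)
    p = 0.5 * (1.0 + erf(z / sqrt(2.0)))
    return RunsTestResult(float(min(max(p, 0.0), 1.0)), n1, n2, runs, False, False)


def runs_test(residuals) -> float:
    """p-value of :func:`runs_test_detail`."""
    return runs_test_detail(residuals).p_value


@dataclass
class QCReport:
    """Per-peptide quality-control outcome at threshold ``alpha``."""

    runs_p: dict[str, float]
    r_squared: dict[str, float]
    pass_per_model: dict[str, bool]
    pass_all_models: bool
    alpha: float = 0.05
    reason: str = ""


def qc_gate(fits: dict, alpha: float = 0.05) -> QCReport:
    """Apply the runs-test gate: per-model pass is runs_p >= alpha; the
    joint pass requires all three models present and all passing."""
    if not fits:
        raise ValueError("no fits to gate")
    runs_p = {m: float(f.runs_p) for m, f in fits.items()}
    r2 = {m: float(f.r_squared) for m, f in fits.items()}
    passes = {m: bool(p >= alpha) for m, p in runs_p.items()}
    complete = len(fits) == 3
    joint = complete and all(passes.values())
    reason = "" if complete else "incomplete"
    if complete and not joint:
        reason = "runs-test failure: " + ",".join(
            m for m, ok in passes.items() if not ok
        )
    return QCReport(runs_p, r2, passes, joint, alpha, reason)
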