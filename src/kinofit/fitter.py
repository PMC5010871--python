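"""Coordinate-wise adaptive-step least-squares fitting of kinetic models.

The optimizer is a deterministic pattern search: parameters are swept
in a fixed order; each proposal ``p_j + s_j`` is kept only if it
strictly decreases the sum of squared deviations (SSE), in which case
the step grows by 1.2; otherwise the step is multiplied by -0.5, so the
search direction reverses while the magnitude halves.  One iteration is
one full sweep.  Fitting stops when the percent change of SSE over a
sweep falls below a threshold (default 6e-5 %) or after a maximum
number of sweeps (default 1000).  Initial steps default to 1/100 of the
starting parameter values, with an absolute fallback for parameters
that start at exactly zero.

The public fitting surface is the scikit-learn style estimator
:class:`KineticCurveFit`; :func:`fit_series` and :func:`fit_all_models`
are thin wrappers used by the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import gof
from ._kernels import descend as _descend_jit
from .models import (
    MODEL_CODES,
    MODELS,
    InitialGuess,
    KinomicSeries,
    ModelSpec,
    eval_model,
    get_model,
    initial_params,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "KineticCurveFit",
    "sse",
    "coordinate_descent",
    "fit_series",
    "fit_all_models",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings, defaulting to the reference tool's values."""

    max_iterations: int = 1000
    initial_step_fraction: float = 1e-2
    min_sse_percent_change: float = 6e-5
    step_growth: float = 1.2
    step_reversal: float = -0.5
    zero_param_step: float = 0.01

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not self.initial_step_fraction > 0:
            raise ValueError("initial_step_fraction must be > 0")
        if not self.min_sse_percent_change > 0:
            raise ValueError("min_sse_percent_change must be > 0")


@dataclass
class FitResult:
    """Outcome of fitting one model to one peptide series."""

    model_id: str
    params: dict[str, float]
    sse: float
    r_squared: float
    runs_p: float
    iterations_used: int
    converged_by: str  # "SSE_CHANGE" | "MAX_ITER"
    degenerate: bool = False
    param_vector: np.ndarray = field(default=None, repr=False)

    def predict(self, c) -> np.ndarray:
        return eval_model(self.model_id, self.param_vector, c)


def sse(series: KinomicSeries, model: str | ModelSpec, params) -> float:
    """Sum of squared deviations of the model from the observed signals."""
    fitted = eval_model(model, params, series.cycles)
    resid = np.asarray(fitted) - series.signals
    return float(np.sum(resid * resid))


def _initial_steps(p0: np.ndarray, config: FitConfig) -> np.ndarray:
    steps = config.initial_step_fraction * p0
    steps[p0 == 0.0] = config.zero_param_step
    return steps


def coordinate_descent(
    fun: Callable[[np.ndarray, np.ndarray], np.ndarray],
    x: np.ndarray,
    y: np.ndarray,
    p0: np.ndarray,
    config: FitConfig = FitConfig(),
    steps: np.ndarray | None = None,
):
    """Generic pure-Python engine for arbitrary model callables.

    ``fun(params, x)`` returns fitted values.  Mirrors the compiled
    kernel decision-for-decision.  Returns
    ``(params, sse, iterations, converged)``.
    """
    p = np.asarray(p0, dtype=float).copy()
    if not np.all(np.isfinite(p)):
        raise ValueError("invalid start: non-finite initial parameters")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s = _initial_steps(p, config) if steps is None else np.asarray(steps, float).copy()

    def objective(params: np.ndarray) -> float:
        with np.errstate(all="ignore"):
            fitted = fun(params, x)
            resid = np.asarray(fitted, dtype=float) - y
            return float(np.sum(resid * resid))

    current = objective(p)
    if not np.isfinite(current):
        raise ValueError("invalid start: non-finite SSE at initial parameters")

    iterations = 0
    converged = False
    for iterations in range(1, config.max_iterations + 1):
        sse_prev = current
        if sse_prev == 0.0:
            converged = True
            iterations -= 1
            break
        for j in range(p.size):
            old = p[j]
            p[j] = old + s[j]
            trial = objective(p)
            if np.isfinite(trial) and trial < current:
                current = trial
                s[j] *= config.step_growth
            else:
                p[j] = old
                s[j] *= config.step_reversal
        if current < sse_prev:
            pct = 100.0 * (sse_prev - current) / sse_prev
            if pct < config.min_sse_percent_change:
                converged = True
                break
    return p, current, iterations, converged


class KineticCurveFit(RegressorMixin, BaseEstimator):
    """Fit one kinetic model to one progress curve, sklearn-style.

    Parameters
    ----------
    model : {"eq1", "eq2", "eq3"}, default "eq3"
        Which kinetic model to fit.
    max_iterations, initial_step_fraction, min_sse_percent_change,
    step_growth, step_reversal, zero_param_step :
        Optimizer settings; see :class:`FitConfig` for the defaults.

    Attributes (after ``fit``)
    --------------------------
    params_ : dict mapping parameter name to fitted value
    param_vector_ : ndarray in the model's sweep order
    sse_ : float, final sum of squared deviations
    r_squared_ : float (NaN for a zero-variance series)
    runs_p_ : one-sided Wald-Wolfowitz runs-test p-value on residuals
    n_iter_ : sweeps used
    converged_by_ : "SSE_CHANGE" or "MAX_ITER"
    degenerate_ : True when the series was uninformative (flat) or the
        fit produced non-finite values

    Examples
    --------
    >>> import numpy as np
    >>> c = np.arange(1.0, 14.0)
    >>> y = 100 * 2 * c / (100 + 2 * c)
    >>> est = KineticCurveFit(model="eq3").fit(c, y)
    >>> round(est.params_["vi"], 2)
    2.0
    """

    def __init__(
        self,
        model: str = "eq3",
        max_iterations: int = 1000,
        initial_step_fraction: float = 1e-2,
        min_sse_percent_change: float = 6e-5,
        step_growth: float = 1.2,
        step_reversal: float = -0.5,
        zero_param_step: float = 0.01,
    ):
        self.model = model
        self.max_iterations = max_iterations
        self.initial_step_fraction = initial_step_fraction
        self.min_sse_percent_change = min_sse_percent_change
        self.step_growth = step_growth
        self.step_reversal = step_reversal
        self.zero_param_step = zero_param_step

    def _config(self) -> FitConfig:
        return FitConfig(
            max_iterations=self.max_iterations,
            initial_step_fraction=self.initial_step_fraction,
            min_sse_percent_change=self.min_sse_percent_change,
            step_growth=self.step_growth,
            step_reversal=self.step_reversal,
            zero_param_step=self.zero_param_step,
        )

    @staticmethod
    def _as_cycles(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("X must be a 1-D cycle vector or an (n, 1) column")
        return X

    def fit(self, X, y, init=None):
        """Fit the model to cycles ``X`` and signals ``y``."""
        cycles = self._as_cycles(X)
        signals = np.asarray(y, dtype=float)
        series = KinomicSeries("", "", cycles, signals)
        result = fit_series(series, self.model, config=self._config(), init=init)
        self.spec_ = get_model(self.model)
        self.params_ = result.params
        self.param_vector_ = result.param_vector
        self.param_names_ = self.spec_.param_names
        self.sse_ = result.sse
        self.r_squared_ = result.r_squared
        self.runs_p_ = result.runs_p
        self.n_iter_ = result.iterations_used
        self.converged_by_ = result.converged_by
        self.degenerate_ = result.degenerate
        self.result_ = result
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "param_vector_"):
            raise AttributeError("estimator is not fitted; call fit first")
        cycles = self._as_cycles(X)
        return np.asarray(eval_model(self.model, self.param_vector_, cycles))


def fit_series(
    series: KinomicSeries,
    model: str | ModelSpec,
    config: FitConfig = FitConfig(),
    init: InitialGuess | np.ndarray | None = None,
) -> FitResult:
    """Fit one model to one series; initial values default to the
    algebraic point-wise estimates of :func:`kinofit.models.initial_params`."""
    spec = get_model(model)
    if len(series) < spec.n_params + 1:
        raise ValueError(
            f"series too short for {spec.model_id}: {len(series)} points, "
            f"need >= {spec.n_params + 1}"
        )
    mask = np.isfinite(series.signals)
    cycles = series.cycles[mask]
    signals = series.signals[mask]
    work = KinomicSeries(series.peptide_id, series.sample_id, cycles, signals)

    degenerate = False
    if init is None:
        init = initial_params(spec, work)
    if isinstance(init, InitialGuess):
        degenerate = init.degenerate
        p0 = np.asarray(init.values, dtype=float)
    else:
        p0 = np.asarray(init, dtype=float)
    if not np.all(np.isfinite(p0)):
        raise ValueError("invalid start: non-finite initial parameters")

    steps = _initial_steps(p0.copy(), config)
    p, _, final_sse, iterations, converged = _descend_jit(
        MODEL_CODES[spec.model_id],
        cycles,
        signals,
        p0,
        steps,
        config.max_iterations,
        config.min_sse_percent_change,
        config.step_growth,
        config.step_reversal,
    )
    if not np.isfinite(final_sse):
        raise ValueError("invalid start: non-finite SSE at initial parameters")

    fitted = np.asarray(eval_model(spec, p, cycles))
    residuals = signals - fitted
    if not np.all(np.isfinite(fitted)):
        degenerate = True
    if np.ptp(signals) == 0.0:
        r2 = float("nan")
        degenerate = True
    else:
        r2 = gof.r_squared(work, fitted)
    runs = gof.runs_test_detail(residuals)
    degenerate = degenerate or runs.degenerate

    return FitResult(
        model_id=spec.model_id,
        params=dict(zip(spec.param_names, map(float, p))),
        sse=float(final_sse),
        r_squared=r2,
        runs_p=runs.p_value,
        iterations_used=int(iterations),
        converged_by="SSE_CHANGE" if converged else "MAX_ITER",
        degenerate=bool(degenerate),
        param_vector=p,
    )


def fit_all_models(
    series: KinomicSeries, config: FitConfig = FitConfig()
) -> dict[str, FitResult]:
    """Fit eq1, eq2 and eq3 to one series.

    A model whose length precondition fails is absent from the map (with
    a logged reason); any other per-model failure is recorded as a
    degenerate placeholder result rather than raised.
    """
    out: dict[str, FitResult] = {}
    for model_id, spec in MODELS.items():
        if len(series) < spec.n_params + 1:
            logger.info(
                "peptide %s: skipping %s (%d points < %d required)",
                series.peptide_id, model_id, len(series), spec.n_params + 1,
            )
            continue
        try:
            out[model_id] = fit_series(series, spec, config=config)
        except Exception as exc:  # degenerate data, invalid start, ...
            logger.warning("peptide %s: %s fit failed: %s",
                           series.peptide_id, model_id, exc)
            out[model_id] = FitResult(
                model_id=model_id,
                params={name: float("nan") for name in spec.param_names},
                sse=float("nan"),
                r_squared=float("nan"),
                runs_p=float("nan"),
                iterations_used=0,
                converged_by="MAX_ITER",
                degenerate=True,
                param_vector=np.full(spec.n_params, np.nan),
            )
    return out
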