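"""Candidate kinetic models for kinome peptide-array progress curves.

Three models describe the accumulation of background-subtracted
phosphorylation signal ``y`` as a function of the instrument's reaction
cycle ``c``:

``eq1``  simple negative exponential
    y = y0 + ymax * (1 - exp(-k * c))

``eq2``  background-corrected (c0) negative exponential
    y = y0 + ymax * (1 - exp(-k * (c - c0)))

``eq3``  background-corrected (c0) rational hyperbolic
    y = ymax * vi * (c - c0) / (ymax + vi * (c - c0))

``ymax`` is the asymptotic signal capacity, ``k`` the exponential rate
(per cycle), ``vi`` the initial slope (signal per cycle) of the
hyperbolic model and ``c0`` a cycle offset absorbing the reaction lag.
The hyperbolic model arises from linear product accumulation
``dy/dc = vi`` saturating at capacity ``ymax``; its reciprocal form
``y = (1/(vi*(c-c0)) + 1/ymax)^-1`` is algebraically identical and kept
here for testing the derivation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MODELS",
    "ModelSpec",
    "KinomicSeries",
    "eval_model",
    "model_limit",
    "v_ini",
    "eq3_alternate_form",
    "initial_params",
]

#: floor applied to rate-like starting values (k, vi) so the optimizer
#: never starts at a frozen zero rate
RATE_FLOOR = 1e-3
#: floor applied to the amplitude starting value (ymax)
AMPLITUDE_FLOOR = 1e-6


@dataclass(frozen=True)
class ModelSpec:
    """One kinetic model: identifier, ordered parameter names, evaluator.

    ``param_names`` order is fixed — it is the order in which the
    coordinate-descent optimizer sweeps the parameters.
    """

    model_id: str
    param_names: tuple[str, ...]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.model_id


MODELS: dict[str, ModelSpec] = {
    "eq1": ModelSpec("eq1", ("y0", "ymax", "k")),
    "eq2": ModelSpec("eq2", ("y0", "ymax", "k", "c0")),
    "eq3": ModelSpec("eq3", ("ymax", "vi", "c0")),
}

#: integer codes used by the numba kernels
MODEL_CODES = {"eq1": 1, "eq2": 2, "eq3": 3}


def get_model(model: str | ModelSpec) -> ModelSpec:
    if isinstance(model, ModelSpec):
        return model
    try:
        return MODELS[model]
    except KeyError:
        raise ValueError(
            f"unknown model {model!r}; expected one of {sorted(MODELS)}"
        ) from None


@dataclass
class KinomicSeries:
    """One peptide's progress curve: (cycle, signal) pairs plus identifiers.

    Signals are background-subtracted fluorescence and may be negative.
    Cycles must be strictly increasing.
    """

    peptide_id: str
    sample_id: str
    cycles: np.ndarray
    signals: np.ndarray

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.cycles.ndim != 1 or self.signals.ndim != 1:
            raise ValueError("cycles and signals must be 1-D")
        if self.cycles.size != self.signals.size:
            raise ValueError(
                f"cycles ({self.cycles.size}) and signals "
                f"({self.signals.size}) differ in length"
            )
        if self.cycles.size and np.any(np.diff(self.cycles) <= 0):
            raise ValueError("cycles must be strictly increasing")
        if not np.all(np.isfinite(self.cycles)):
            raise ValueError("cycles must be finite")

    def __len__(self) -> int:
        return self.cycles.size


def _params_array(spec: ModelSpec, params) -> np.ndarray:
    """Accept a dict keyed by parameter name or an ordered sequence."""
    if isinstance(params, dict):
        try:
            arr = np.array([params[name] for name in spec.param_names], float)
        except KeyError as exc:
            raise ValueError(f"missing parameter {exc} for {spec.model_id}")
    else:
        arr = np.asarray(params, dtype=float)
        if arr.shape != (spec.n_params,):
            raise ValueError(
                f"{spec.model_id} expects {spec.n_params} parameters, "
                f"got shape {arr.shape}"
            )
    return arr


def eval_model(model: str | ModelSpec, params, c):
    """Evaluate a model at cycle(s) ``c``.

    Values for ``c < c0`` are evaluated exactly as the equations read —
    no clamping; callers decide any masking.  For ``eq3`` a vanishing
    denominator ``ymax + vi*(c - c0)`` signals degenerate parameters and
    raises ``ZeroDivisionError``.
    """
    spec = get_model(model)
    p = _params_array(spec, params)
    c = np.asarray(c, dtype=float)
    if spec.model_id == "eq1":
        y0, ymax, k = p
        out = y0 + ymax * (1.0 - np.exp(-k * c))
    elif spec.model_id == "eq2":
        y0, ymax, k, c0 = p
        out = y0 + ymax * (1.0 - np.exp(-k * (c - c0)))
    else:
        ymax, vi, c0 = p
        num = vi * (c - c0)
        den = ymax + num
        if np.any(den == 0.0):
            raise ZeroDivisionError(
                "eq3 denominator ymax + vi*(c - c0) vanishes: "
                "degenerate parameters"
            )
        out = ymax * num / den
    return out if out.ndim else float(out)


def model_limit(model: str | ModelSpec, params) -> float:
    """The c -> infinity asymptote of the model.

    ``y0 + ymax`` for the exponentials, ``ymax`` for the hyperbola.
    Requires a positive rate parameter (k or vi); otherwise the
    asymptote does not exist and a ``ValueError`` is raised.
    """
    spec = get_model(model)
    p = _params_array(spec, params)
    named = dict(zip(spec.param_names, p))
    rate = named["vi"] if spec.model_id == "eq3" else named["k"]
    if not rate > 0:
        raise ValueError(
            f"{spec.model_id} asymptote undefined for non-positive rate "
            f"parameter ({rate})"
        )
    if spec.model_id == "eq3":
        return float(named["ymax"])
    return float(named["y0"] + named["ymax"])


def v_ini(params, c_eval: float = 35.0) -> float:
    """Early-reaction slope from the eq2 fit: y'(c_eval).

    v_ini = ymax * k * exp(-k * (c_eval - c0)), evaluated by default at
    cycle 35, the convention used when array studies report a single
    initial-velocity statistic per peptide.
    """
    spec = MODELS["eq2"]
    p = _params_array(spec, params)
    _, ymax, k, c0 = p
    if not np.all(np.isfinite(p)):
        raise ValueError("non-finite eq2 parameters")
    return float(ymax * k * math.exp(-k * (c_eval - c0)))


def eq3_alternate_form(params, c):
    """Reciprocal form of the hyperbolic model: ((vi*(c-c0))^-1 + ymax^-1)^-1.

    Exists to test the derivation identity with the rational form; it
    requires ``vi*(c-c0) > 0`` and ``ymax > 0``.
    """
    spec = MODELS["eq3"]
    ymax, vi, c0 = _params_array(spec, params)
    c = np.asarray(c, dtype=float)
    num = vi * (c - c0)
    if np.any(num <= 0) or not ymax > 0:
        raise ValueError(
            "reciprocal form requires vi*(c - c0) > 0 and ymax > 0"
        )
    out = 1.0 / (1.0 / num + 1.0 / ymax)
    return out if out.ndim else float(out)


@dataclass
class InitialGuess:
    """Starting parameter vector plus a degeneracy flag."""

    values: np.ndarray
    degenerate: bool = False
    param_names: tuple[str, ...] = field(default=())

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.param_names, map(float, self.values)))


def initial_params(model: str | ModelSpec, series: KinomicSeries) -> InitialGuess:
    """Algebraic starting values for the optimizer, from individual points.

    Rules (deterministic, seedless):

    * ``c0``   <- first cycle (eq2/eq3)
    * ``y0``   <- first signal (eq1/eq2)
    * ``ymax`` <- 1.5 * (max signal - min signal), floored
    * ``vi``   <- slope between the first adjacent pair of points with a
      positive signal change, floored
    * ``k``    <- solved algebraically from the mid-series point given
      the other starting values, floored

    A flat (all-equal) series carries no kinetic information: floor
    values are returned with ``degenerate=True``.
    """
    spec = get_model(model)
    c = series.cycles
    y = series.signals
    if len(series) < spec.n_params + 1:
        raise ValueError(
            f"series of length {len(series)} too short to fit "
            f"{spec.model_id} ({spec.n_params} parameters)"
        )
    finite = np.isfinite(y)
    if not finite.all():
        c, y = c[finite], y[finite]
        if c.size < spec.n_params + 1:
            raise ValueError("too few finite points after masking")

    degenerate = bool(np.ptp(y) == 0.0)
    c0 = float(c[0])
    y0 = float(y[0])
    ymax = max(1.5 * float(np.ptp(y)), AMPLITUDE_FLOOR)

    if spec.model_id == "eq3":
        vi = RATE_FLOOR
        dy = np.diff(y)
        pos = np.nonzero(dy > 0)[0]
        if pos.size:
            i = pos[0]
            vi = max(float(dy[i] / (c[i + 1] - c[i])), RATE_FLOOR)
        values = np.array([ymax, vi, c0])
        return InitialGuess(values, degenerate, spec.param_names)

    # eq1 / eq2: solve the mid-series point for k
    offset = 0.0 if spec.model_id == "eq1" else c0
    mid = c.size // 2
    k = RATE_FLOOR
    dc = c[mid] - offset
    if dc > 0:
        frac = (y[mid] - y0) / ymax
        if 0.0 < frac < 1.0:
            k = max(-math.log(1.0 - frac) / dc, RATE_FLOOR)
    if spec.model_id == "eq1":
        values = np.array([y0, ymax, k])
    else:
        values = np.array([y0, ymax, k, c0])
    return InitialGuess(values, degenerate, spec.param_names)
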