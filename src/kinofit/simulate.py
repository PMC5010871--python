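"""Synthetic kinome-array datasets with known ground truth.

Real array exports are proprietary, so testing the fitting, QC and
reproducibility machinery requires curves whose true kinetics are
known.  The generator emulates the instrument's output shape: 13-point
progress curves per peptide (background-subtracted signal vs. reaction
cycle), 144 peptides per chip, optional technical replicates sharing
per-peptide truth with independent noise, and a configurable fraction
of peptides whose capacity ``ymax`` far exceeds the observable signal
range — curves that remain in a near-linear phase over the recorded
cycles, a prominent feature of real chips.

Noise is additive homoscedastic Gaussian by default (background
subtraction can undershoot, so negative signals are retained); a
signal-proportional component is available for robustness studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import MODELS, KinomicSeries, eval_model, get_model

__all__ = ["ChipSimConfig", "simulate_series", "simulate_chip", "DEFAULT_CYCLES"]

#: default 13-point cycle grid spanning the early-linear through bending
#: regimes of typical chips
DEFAULT_CYCLES = (3, 8, 12, 17, 22, 27, 32, 36, 41, 46, 51, 55, 60)

#: default per-parameter priors; (low, high, "log") is log-uniform.
#: Kinetic-regime hyperbolic curves are drawn by capacity ``ymax`` and
#: saturation ratio ``bend`` = vi*(c_max - c0)/ymax, so the chip spans
#: half-saturating through strongly saturating curves by construction;
#: ``vi`` is derived unless a ``vi`` prior is supplied explicitly.
DEFAULT_PRIORS = {
    "ymax": (200.0, 2000.0, "log"),
    "bend": (0.5, 10.0, "log"),
    "vi": (2.0, 30.0, "log"),
    "k": (0.005, 0.1, "log"),
    "c0": (0.0, 3.0, "lin"),
    "y0": (-10.0, 10.0, "lin"),
}


@dataclass
class ChipSimConfig:
    """Study conditions for one simulated chip experiment."""

    n_peptides: int = 144
    cycles: tuple = DEFAULT_CYCLES
    true_model: str = "eq3"
    parameter_priors: dict = field(default_factory=dict)
    noise_sd: float = 10.0
    noise_fraction: float = 0.0
    fraction_linear_phase: float = 0.25
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.fraction_linear_phase <= 1.0:
            raise ValueError("fraction_linear_phase must be in [0, 1]")
        cyc = np.asarray(self.cycles, dtype=float)
        if np.any(np.diff(cyc) <= 0):
            raise ValueError("cycles must be strictly increasing")


def _draw(rng: np.random.Generator, low: float, high: float, kind: str) -> float:
    if kind == "log":
        return float(np.exp(rng.uniform(np.log(low), np.log(high))))
    return float(rng.uniform(low, high))


def _draw_truth(config: ChipSimConfig, rng: np.random.Generator,
                linear_phase: bool) -> np.ndarray:
    """True parameter vector in the model's sweep order."""
    spec = get_model(config.true_model)
    priors = {**DEFAULT_PRIORS, **config.parameter_priors}
    p = {name: _draw(rng, *priors[name]) for name in spec.param_names}
    c_max = float(max(config.cycles))
    span = c_max - p.get("c0", 0.0)
    if spec.model_id == "eq3" and not linear_phase:
        if "vi" in config.parameter_priors:
            pass  # explicit prior takes precedence over the bend draw
        else:
            p["vi"] = _draw(rng, *priors["bend"]) * p["ymax"] / span
    if linear_phase:
        if spec.model_id == "eq3":
            # capacity >= 10x the achievable signal range vi*span
            p["ymax"] = rng.uniform(10.0, 50.0) * p["vi"] * span
        else:
            # near-linear exponential: k*span <= ~0.1 so the curve bends
            # imperceptibly; keep the observed slope ymax*k realistic
            slope = _draw(rng, *priors["vi"])
            p["k"] = rng.uniform(0.02, 0.1) / span
            p["ymax"] = slope / p["k"]
    return np.array([p[name] for name in spec.param_names])


def simulate_series(
    config: ChipSimConfig,
    true_params,
    rng: np.random.Generator | None = None,
    peptide_id: str = "pep",
    sample_id: str = "sim",
) -> KinomicSeries:
    """One noisy progress curve from known true parameters."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cycles = np.asarray(config.cycles, dtype=float)
    truth = np.asarray(eval_model(config.true_model, true_params, cycles))
    signals = truth + rng.normal(0.0, config.noise_sd, size=cycles.size)
    if config.noise_fraction > 0.0:
        signals = signals + rng.normal(
            0.0, config.noise_fraction * np.abs(truth)
        )
    return KinomicSeries(peptide_id, sample_id, cycles, signals)


def simulate_chip(
    config: ChipSimConfig,
) -> tuple[list[KinomicSeries], pd.DataFrame]:
    """A full chip: ``n_peptides`` curves per replicate, replicates
    sharing per-peptide truth, plus a truth table keyed by peptide_id.

    The first ``round(fraction_linear_phase * n_peptides)`` peptides are
    drawn in the near-linear regime (unbounded-looking ymax).  Output is
    fully determined by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    spec = get_model(config.true_model)
    n_linear = int(round(config.fraction_linear_phase * config.n_peptides))
    width = max(3, len(str(config.n_peptides)))

    truths = []
    rows = []
    for i in range(config.n_peptides):
        linear = i < n_linear
        p = _draw_truth(config, rng, linear)
        pid = f"pep{i + 1:0{width}d}"
        truths.append((pid, p, linear))
        row = {"peptide_id": pid, "model": spec.model_id,
               "linear_phase": linear}
        row.update(dict(zip(spec.param_names, map(float, p))))
        rows.append(row)
    truth_table = pd.DataFrame(rows).set_index("peptide_id")

    series: list[KinomicSeries] = []
    for r in range(config.n_replicates):
        sample = f"rep{r + 1:02d}"
        for pid, p, _ in truths:
            series.append(
                simulate_series(config, p, rng=rng,
                                peptide_id=pid, sample_id=sample)
            )
    return series, truth_table
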