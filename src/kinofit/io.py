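"""Tabular input/output and the batch fitting pipeline.

Two text layouts are accepted, covering common array-software exports:

* ``wide`` — first column is the cycle number, one additional column
  per peptide.
* ``long`` — columns ``peptide_id, cycle, signal``.

Missing values are allowed and masked per peptide; duplicated
(peptide, cycle) observations and non-numeric signal cells are parse
errors that name the offending row/column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitter import FitConfig, fit_all_models
from .gof import qc_gate
from .models import MODELS, KinomicSeries

__all__ = ["Dataset", "read_dataset", "write_dataset", "run_pipeline",
           "PipelineResult"]

logger = logging.getLogger(__name__)

_ALL_PARAMS = ("y0", "ymax", "k", "vi", "c0")


@dataclass
class Dataset:
    """One sample's signal matrix: peptides x shared cycle grid."""

    sample_id: str
    peptide_ids: list[str]
    cycles: np.ndarray
    signals: np.ndarray  # shape (n_peptides, n_cycles)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.shape != (len(self.peptide_ids), self.cycles.size):
            raise ValueError(
                f"signal matrix {self.signals.shape} inconsistent with "
                f"{len(self.peptide_ids)} peptides x {self.cycles.size} cycles"
            )
        if self.cycles.size and np.any(np.diff(self.cycles) <= 0):
            raise ValueError("cycles must be strictly increasing")

    def to_series(self) -> list[KinomicSeries]:
        return [
            KinomicSeries(pid, self.sample_id, self.cycles, row)
            for pid, row in zip(self.peptide_ids, self.signals)
        ]


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def _numeric(frame: pd.DataFrame, columns) -> pd.DataFrame:
    """Coerce columns to float; empty cells become NaN, anything else
    non-numeric is a parse error naming the cell."""
    out = frame.copy()
    for col in columns:
        raw = frame[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = coerced.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric value {raw.iloc[row]!r} in column "
                f"{col!r}, data row {row}"
            )
        out[col] = coerced
    return out


def read_dataset(path, layout: str = "wide", sample_id: str | None = None) -> Dataset:
    """Read one sample's curves from a CSV/TSV file."""
    sep = _sniff_sep(path)
    if layout == "wide":
        with open(path) as fh:
            names = [c.strip() for c in fh.readline().rstrip("\n").split(sep)]
        dupes = {n for n in names[1:] if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicated peptide columns: {sorted(dupes)}")
        frame = pd.read_csv(path, sep=sep)
        frame.columns = names
        frame = _numeric(frame, names)
        cycles = frame[names[0]].to_numpy()
        if np.any(~np.isfinite(cycles)):
            raise ValueError(f"missing cycle value in column {names[0]!r}")
        if np.any(np.diff(cycles) <= 0):
            raise ValueError("cycle column must be strictly increasing")
        peptides = names[1:]
        signals = frame[peptides].to_numpy().T
    elif layout == "long":
        frame = pd.read_csv(path, sep=sep)
        required = ["peptide_id", "cycle", "signal"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(f"long layout requires columns {required}; "
                             f"missing {missing}")
        frame = _numeric(frame, ["cycle", "signal"])
        dup = frame.duplicated(subset=["peptide_id", "cycle"])
        if dup.any():
            row = frame[dup].iloc[0]
            raise ValueError(
                f"duplicated (peptide, cycle) observation: "
                f"({row['peptide_id']}, {row['cycle']})"
            )
        wide = frame.pivot(index="cycle", columns="peptide_id",
                           values="signal").sort_index()
        cycles = wide.index.to_numpy(dtype=float)
        peptides = [str(p) for p in wide.columns]
        signals = wide.to_numpy().T
    else:
        raise ValueError("layout must be 'wide' or 'long'")
    sid = sample_id or str(getattr(path, "stem", None) or str(path))
    return Dataset(sid, list(peptides), cycles, signals,
                   provenance={"source": str(path), "layout": layout})


def write_dataset(dataset: Dataset, path, layout: str = "wide") -> None:
    if layout == "wide":
        frame = pd.DataFrame(dataset.signals.T, columns=dataset.peptide_ids)
        frame.insert(0, "cycle", dataset.cycles)
        frame.to_csv(path, index=False)
    elif layout == "long":
        rows = []
        for pid, row in zip(dataset.peptide_ids, dataset.signals):
            for c, y in zip(dataset.cycles, row):
                rows.append({"peptide_id": pid, "cycle": c, "signal": y})
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise ValueError("layout must be 'wide' or 'long'")


def series_to_datasets(series: list[KinomicSeries]) -> list[Dataset]:
    """Group a flat series collection into per-sample Datasets."""
    by_sample: dict[str, list[KinomicSeries]] = {}
    for s in series:
        by_sample.setdefault(s.sample_id, []).append(s)
    out = []
    for sid, group in by_sample.items():
        cycles = group[0].cycles
        out.append(Dataset(sid, [g.peptide_id for g in group], cycles,
                           np.vstack([g.signals for g in group])))
    return out


@dataclass
class PipelineResult:
    fit_table: pd.DataFrame
    qc_table: pd.DataFrame
    summary: dict


def _coerce_series(data) -> list[KinomicSeries]:
    if isinstance(data, Dataset):
        return data.to_series()
    if isinstance(data, KinomicSeries):
        return [data]
    out: list[KinomicSeries] = []
    for item in data:
        out.extend(_coerce_series(item))
    return out


def run_pipeline(
    data,
    config: FitConfig = FitConfig(),
    alpha: float = 0.05,
) -> PipelineResult:
    """Fit all three models to every series and apply the QC gate.

    ``data`` may be a Dataset, a list of Datasets, or KinomicSeries.
    Individual peptide failures are logged and recorded as degenerate
    rows; they never abort the run.  The summary reports the total
    series count, per-model fit and QC-pass counts, and the fraction of
    series passing the joint (all-three-models) gate.
    """
    series = _coerce_series(data)
    fit_rows: list[dict] = []
    qc_rows: list[dict] = []
    n_joint_pass = 0
    model_fitted = {m: 0 for m in MODELS}
    model_pass = {m: 0 for m in MODELS}

    for s in series:
        try:
            fits = fit_all_models(s, config=config)
        except Exception as exc:  # pragma: no cover - defensive
            logger.error("sample %s peptide %s: pipeline failure: %s",
                         s.sample_id, s.peptide_id, exc)
            fits = {}
        report = qc_gate(fits, alpha=alpha) if fits else None
        if report is not None and report.pass_all_models:
            n_joint_pass += 1
        for model_id, fr in fits.items():
            row = {
                "sample_id": s.sample_id,
                "peptide_id": s.peptide_id,
                "model": model_id,
            }
            for name in _ALL_PARAMS:
                row[name] = fr.params.get(name, float("nan"))
            row.update(
                sse=fr.sse, r_squared=fr.r_squared, runs_p=fr.runs_p,
                iterations=fr.iterations_used, converged_by=fr.converged_by,
                degenerate=fr.degenerate,
            )
            fit_rows.append(row)
            if not fr.degenerate:
                model_fitted[model_id] += 1
            passed = report.pass_per_model[model_id] if report else False
            if passed:
                model_pass[model_id] += 1
            qc_rows.append({
                "sample_id": s.sample_id,
                "peptide_id": s.peptide_id,
                "model": model_id,
                "sse": fr.sse,
                "r2": fr.r_squared,
                "runs_p": fr.runs_p,
                "pass": passed,
                "pass_all_models": bool(report.pass_all_models) if report else False,
            })

    fit_table = pd.DataFrame(fit_rows)
    qc_table = pd.DataFrame(qc_rows)
    n_series = len(series)
    summary = {
        "n_series": n_series,
        "n_fits": len(fit_rows),
        "fits_per_model": model_fitted,
        "qc_pass_per_model": model_pass,
        "joint_qc_pass": n_joint_pass,
        "joint_qc_pass_fraction": (n_joint_pass / n_series) if n_series else 0.0,
        "alpha": alpha,
    }
    return PipelineResult(fit_table, qc_table, summary)
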