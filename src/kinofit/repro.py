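"""Technical-replicate reproducibility of fitted kinetic parameters.

A technical replicate re-assays the same lysate: true kinetics are
shared, noise is independent, so a reproducible parameter should agree
in rank across replicates.  Raw estimates are first made nonparametric
by replacing each value with its quantile (rank/n, average ranks for
ties); paired replicate estimates are then compared by Spearman rank
correlation ("quantile-quantile correlation").  Pairing covers every
unordered pair of replicates within a set, restricted to peptides whose
fits pass QC in both members of the pair for the model in question.
Density summaries use a Gaussian-kernel KDE with the Parzen-Rosenblatt
rule-of-thumb bandwidth h = 1.06 * sigma * n^(-1/5).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .models import v_ini as _v_ini

__all__ = [
    "ReplicateStudy",
    "quantile_transform",
    "qq_correlation",
    "pair_replicates",
    "kde_density",
]

#: parameters that can be paired; v_ini is derived from eq2 fits
PAIRABLE = ("k", "ymax", "vi", "y0", "c0", "v_ini")


def quantile_transform(values) -> np.ndarray:
    """Replace raw values by their quantiles rank/n in (0, 1].

    Ties receive average ranks, so (5, 5) maps to (0.75, 0.75).
    Order-preserving: a strictly increasing input yields strictly
    increasing quantiles.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to assign quantiles")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values cannot be ranked")
    return stats.rankdata(v, method="average") / v.size


def qq_correlation(a, b) -> float:
    """Spearman rank correlation of paired replicate estimates.

    Equals the Pearson correlation of the quantile-transformed values
    when ties are absent.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired vectors differ in length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise ValueError("constant vector: rank correlation undefined")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


@dataclass
class ReplicateStudy:
    """Replicate structure: sets of replicates, each a mapping
    peptide_id -> {model_id -> FitResult}.

    ``replicate_sets`` is a list of sets; each set is a list of
    replicates (e.g. two sets of 6 technical replicates).
    """

    replicate_sets: list[list[dict[str, dict]]]
    alpha: float = 0.05
    v_ini_cycle: float = 35.0
    paired_quantiles: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False
    )


def _extract(fits_by_peptide: dict, peptide: str, model_id: str,
             parameter: str, alpha: float, v_ini_cycle: float):
    """Parameter value for one peptide in one replicate, or None if the
    fit is absent, degenerate, or fails per-model QC."""
    fits = fits_by_peptide.get(peptide)
    if not fits or model_id not in fits:
        return None
    fr = fits[model_id]
    if fr.degenerate or not np.isfinite(fr.runs_p) or fr.runs_p < alpha:
        return None
    if parameter == "v_ini":
        value = _v_ini(fr.param_vector, c_eval=v_ini_cycle)
    else:
        value = fr.params.get(parameter)
        if value is None:
            raise ValueError(
                f"model {model_id} has no parameter {parameter!r}"
            )
    return value if np.isfinite(value) else None


def pair_replicates(
    study: ReplicateStudy, model_id: str, parameter: str
) -> tuple[np.ndarray, np.ndarray]:
    """All within-set replicate pairs of one parameter's estimates.

    For every unordered pair of replicates in each set and every peptide
    whose fit passes QC (runs_p >= alpha, non-degenerate) in both pair
    members, emit the two estimates.  ``v_ini`` is computed from the
    eq2 parameters before pairing.  Returns two equal-length vectors;
    empty vectors mean no pair survived.
    """
    if parameter not in PAIRABLE:
        raise ValueError(f"parameter must be one of {PAIRABLE}")
    left: list[float] = []
    right: list[float] = []
    for replicate_set in study.replicate_sets:
        if len(replicate_set) < 2:
            raise ValueError("each replicate set needs >= 2 replicates")
        peptides = sorted(
            {pep for rep in replicate_set for pep in rep}
        )
        for rep_a, rep_b in combinations(replicate_set, 2):
            for pep in peptides:
                va = _extract(rep_a, pep, model_id, parameter,
                              study.alpha, study.v_ini_cycle)
                vb = _extract(rep_b, pep, model_id, parameter,
                              study.alpha, study.v_ini_cycle)
                if va is not None and vb is not None:
                    left.append(va)
                    right.append(vb)
    a, b = np.asarray(left), np.asarray(right)
    if a.size:
        study.paired_quantiles = (quantile_transform(a), quantile_transform(b))
    else:
        study.paired_quantiles = None
    return a, b


def replicate_correlation(
    study: ReplicateStudy, model_id: str, parameter: str
) -> float:
    """qq_correlation of all surviving replicate pairs (NaN if none)."""
    a, b = pair_replicates(study, model_id, parameter)
    if a.size < 3:
        return float("nan")
    return qq_correlation(a, b)


def study_from_fit_table(
    fit_table, alpha: float = 0.05, set_column: str | None = None
) -> ReplicateStudy:
    """Build a ReplicateStudy from a pipeline fit table.

    Each distinct ``sample_id`` becomes one replicate.  Replicates all
    fall in a single set unless ``set_column`` names a column assigning
    each row to a replicate set.
    """
    from .fitter import FitResult  # local import to avoid a cycle

    param_cols = ("y0", "ymax", "k", "vi", "c0")
    sets: dict[str, dict[str, dict[str, dict]]] = {}
    for _, row in fit_table.iterrows():
        set_key = str(row[set_column]) if set_column else "all"
        rep = sets.setdefault(set_key, {}).setdefault(str(row["sample_id"]), {})
        model_id = str(row["model"])
        from .models import MODELS as _MODELS

        spec = _MODELS[model_id]
        params = {n: float(row[n]) for n in param_cols
                  if n in row and np.isfinite(row.get(n, np.nan))}
        vec = np.array([params.get(n, np.nan) for n in spec.param_names])
        rep.setdefault(str(row["peptide_id"]), {})[model_id] = FitResult(
            model_id=model_id,
            params=params,
            sse=float(row.get("sse", np.nan)),
            r_squared=float(row.get("r_squared", np.nan)),
            runs_p=float(row.get("runs_p", np.nan)),
            iterations_used=int(row.get("iterations", 0)),
            converged_by=str(row.get("converged_by", "")),
            degenerate=bool(row.get("degenerate", False)),
            param_vector=vec,
        )
    replicate_sets = [
        [reps[sid] for sid in sorted(reps)] for _, reps in sorted(sets.items())
    ]
    return ReplicateStudy(replicate_sets, alpha=alpha)


def kde_density(values, grid) -> np.ndarray:
    """Gaussian-kernel density with the rule-of-thumb bandwidth
    h = 1.06 * sigma * n^(-1/5), evaluated on ``grid``."""
    v = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if np.unique(v).size < 2:
        raise ValueError("need >= 2 distinct values for a density")
    n = v.size
    sigma = float(np.std(v, ddof=1))
    h = 1.06 * sigma * n ** (-0.2)
    z = (grid[:, None] - v[None, :]) / h
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (n * h * np.sqrt(2.0 * np.pi))
    return dens
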