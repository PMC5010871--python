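# Methods

## The measurement and the models

Kinome peptide arrays expose ~144 phosphorylatable peptides to a cell
lysate and record, at each reaction cycle `c`, a background-subtracted
fluorescence signal `y` proportional to accumulated phosphorylation.
Each peptide yields a short progress curve (13 points in the regime this
package targets). Three candidate models describe such a curve:

| id  | equation | parameters (sweep order) |
|-----|----------|--------------------------|
| eq1 | `y = y0 + ymax (1 − e^{−k c})` | `y0, ymax, k` |
| eq2 | `y = y0 + ymax (1 − e^{−k (c − c0)})` | `y0, ymax, k, c0` |
| eq3 | `y = ymax vi (c − c0) / (ymax + vi (c − c0))` | `ymax, vi, c0` |

`ymax` (signal units) is the asymptotic capacity, `k` (per cycle) the
exponential rate, `vi` (signal/cycle) the initial slope of the
hyperbola, and `c0` (cycles) a lag offset. eq3 follows from linear
product accumulation `dy/dc = vi` throttled by the fraction of remaining
capacity, giving the reciprocal form
`y = (1/(vi (c − c0)) + 1/ymax)^{-1}`, algebraically identical to the
rational form (the package keeps both and tests their agreement to 4
ulp). The cycle index is used directly as the independent variable; no
conversion to wall-clock time is attempted.

The summary statistic `v_ini = y'(35) = ymax · k · e^{−k (35 − c0)}` is
the eq2 curve's slope at cycle 35. The evaluation cycle defaults to 35
— the convention in array studies — but is a function argument, since
nothing in the kinetics singles that cycle out.

## Curve fitting

The optimizer is a deterministic coordinate-wise adaptive pattern
search. Parameters are swept in the fixed order above; for parameter
`j` with step `s_j`, the proposal `p_j + s_j` is accepted only on a
strict SSE decrease, whereupon `s_j ← 1.2 s_j`; on rejection the
parameter is restored and `s_j ← −0.5 s_j` (direction reverses,
magnitude halves). One iteration is one full sweep. Defaults:
`max_iterations = 1000`, initial step = 1/100 of each starting value
(absolute 0.01 for parameters starting at exactly 0, which would
otherwise be frozen), and a minimum SSE percent change of `6e−5 %`.
Proposals producing non-finite model values or SSE are rejected, which
keeps the search inside the feasible region (e.g. away from the eq3
pole) without explicit bounds.

Termination: the percent change `100 (SSE_prev − SSE_cur)/SSE_prev`
across a sweep is compared with the threshold only for sweeps that
achieved an improvement; a sweep that rejects every proposal only
shrinks the steps and the search continues. This matters: ridge-shaped
eq3 problems routinely produce an all-rejected sweep while still 5–20 %
from the optimum, and stopping there (the naive reading of a
"percent-change" rule) strands the fit. Because every rejection halves
a step, the search after such sweeps resumes with finer steps and
terminates once real improvements fall under the threshold, or at the
iteration cap. Zero SSE terminates immediately. The algorithm contains
no randomness: identical inputs give bit-identical results.

Starting values are algebraic, deterministic and seedless: `c0` ← first
cycle, `y0` ← first signal, `ymax` ← 1.5 × signal range (floored at
1e−6), `vi` ← slope of the first rising adjacent pair (floored at
1e−3), and `k` solved from the mid-series point given the other starts
(same floor). Flat series carry no kinetic information and are returned
flagged degenerate with floor values.

The three built-in models run through a numba-compiled kernel; a
generic pure-Python engine with the same decision sequence accepts
arbitrary model callables (used for oracle comparisons on linear
problems) and is tested for agreement with the kernel. On convex
problems the search matches a dense grid oracle's SSE within 1 %, and
on noiseless hyperbolic chips it recovers `vi` within 1 % for every
peptide — indistinguishable from a Levenberg–Marquardt reference.

The public fitting surface is a scikit-learn-style estimator
(`KineticCurveFit`), so fits compose with sklearn tooling; the batch
pipeline wraps it per peptide and model.

## Goodness of fit and quality control

Each fit reports `R² = 1 − SSE/SStot` and a Wald–Wolfowitz runs test on
the residual signs. The test is one-sided toward too few runs: lack of
fit shows up as long same-signed residual stretches, while "too many
runs" is not evidence against the model. Zero residuals are dropped
before counting. For `n1 + n2 ≤ 30` (13-point curves always) the
p-value is the exact conditional CDF `P(Runs ≤ R_obs | n1, n2)`; beyond
that a continuity-corrected normal approximation is used. Note the
conditional test is blind to the single-sign configuration (`n1 = 0` or
`n2 = 0` forces `Runs = 1` with probability one, hence p = 1); with
floating-point fits this configuration essentially never occurs.

A peptide passes per-model QC when `runs_p ≥ α` (default 0.05); the
joint gate additionally requires all three models present and passing.
Because the exact test is discrete it is conservative: under the true
model with iid Gaussian noise the rejection rate at α = 0.05 measures
~1 %, comfortably under the nominal level. No multiple-testing
correction is applied across peptides — the gate is a per-curve filter,
not an inference. The gate is meaningful only on noisy data: noiseless
fits leave deterministic numerical-precision residual patterns that the
runs test rightly rejects.

## Replicate reproducibility

Technical replicates share true kinetics with independent noise, so a
useful parameter should agree in rank across replicates. Estimates are
quantile-transformed (rank/n, average ranks on ties — an order-
preserving choice that leaves Spearman correlation untouched) and every
unordered pair of replicates within a set contributes, per peptide, a
paired observation — restricted to peptides passing per-model QC in
both pair members. `v_ini` is computed from the eq2 parameters before
pairing. The reported quantity is the Spearman correlation of the
pooled pairs ("q–q correlation"). Pooling all within-set pairs is a
parameterized choice; per-set correlations can be had by building one
study per set.

On simulated 6-replicate studies the orderings expected from the
kinetics emerge robustly: `vi` (eq3) is more reproducible than `k`
(eq2, whose rate is confounded with capacity on curves far from
saturation), and `v_ini` — a slope, not a rate — is at least as
reproducible as the `k` used to compute it.

Density summaries use a Gaussian-kernel KDE with the Parzen–Rosenblatt
rule-of-thumb bandwidth `h = 1.06 σ̂ n^{−1/5}`.

## Synthetic data generator

The generator emulates the statistical shape of array exports, not the
instrument: per-peptide curves on a shared 13-point cycle grid
(default `3, 8, 12, …, 60`, a stand-in since real cycle schedules vary
by protocol), additive homoscedastic Gaussian noise (default
`noise_sd = 10` signal units, about 2 % of the default prior's median
capacity; an optional signal-proportional component exists for
robustness studies), negatives retained as background subtraction can
undershoot, and optional technical replicates sharing per-peptide truth.

Kinetic-regime eq3 peptides are drawn by capacity
(`ymax` ~ log-uniform [200, 2000]) and saturation ratio
`bend = vi (c_max − c0)/ymax` ~ log-uniform [0.5, 10], with `vi`
derived; `c0` ~ uniform [0, 3]. Drawing the saturation ratio directly
guarantees the chip spans half-saturating through strongly saturating
curves — the regime in which 13 points identify `vi` — rather than
leaving curvature to chance combinations of independent priors. A
configurable fraction (default 25 %) of peptides is instead generated
in the near-linear phase, with `ymax` inflated 10–50× the observable
range: these reproduce the hallmark instability of fitted `ymax`
("capacity far beyond the data") seen on real chips. Exponential truth
uses `k` ~ log-uniform [0.005, 0.1] and `y0` ~ uniform [−10, 10]. A
user-supplied `vi` prior overrides the bend-based draw.

What passing tests on this generator do **not** show about real data:
real arrays have spatially structured and heteroscedastic noise,
washout artifacts, occasional non-monotone curves, and peptide-specific
kinase mixtures; none of these are modeled. The generator validates the
machinery (optimizer, QC calibration, reproducibility pipeline), not
instrument-specific performance.

## Numerical choices and scales

- Exact runs-test CDF via binomial counts; crossover to the normal
  approximation at `n1 + n2 > 30`.
- The `v_ini` vs finite-difference agreement (1e−6 relative, step 1e−4)
  is checked where `k (35 − c0) ≤ 5`; beyond that the slope at cycle 35
  underflows relative to the signal and a double-precision centered
  difference cannot resolve it (the analytic formula evaluates fine
  everywhere).
- Problem sizes used by the test-suite and acceptance computations:
  full 36 × 144 chips for structural counts; 1000 curves for QC
  calibration; 144-peptide chips for recovery; ten 6 × 144 replicate
  batches for the reproducibility ordering. These sizes give
  Monte-Carlo margins well inside the asserted tolerances.
- Length preconditions: a model with `m` parameters requires at least
  `m + 1` points, so a 4-point series fits eq1/eq3 but not eq2.

## Known limitations

- The coordinate search is a local optimizer; pathological starts can
  end in local minima. The algebraic initializer makes this rare on
  array-like curves but no global guarantee exists.
- `ymax` is reported as fitted even when unidentifiable (near-linear
  curves); consumers should treat it as descriptive, not comparative.
- The conditional runs test cannot flag a fit whose residuals are all
  of one sign, and on `n = 13` points its discreteness makes it
  conservative.
- CSV layouts cover common exports; vendor-proprietary formats are out
  of scope.
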