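import numpy as np
import pytest

from kinofit.models import KinomicSeries, eval_model


@pytest.fixture
def cycles13():
    return np.arange(1.0, 14.0)


@pytest.fixture
def eq3_truth():
    """Reference hyperbolic parameters (ymax, vi, c0)."""
    return np.array([100.0, 2.0, 0.0])


@pytest.fixture
def noiseless_eq3_series(cycles13, eq3_truth):
    y = np.asarray(eval_model("eq3", eq3_truth, cycles13))
    return KinomicSeries("pep", "sample", cycles13, y)


def make_series(model, params, cycles, noise_sd=0.0, rng=None,
                peptide_id="pep", sample_id="s"):
    y = np.asarray(eval_model(model, params, cycles), dtype=float)
    if noise_sd:
        y = y + (rng or np.random.default_rng(0)).normal(0, noise_sd, cycles.size)
    return KinomicSeries(peptide_id, sample_id, cycles, y)
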