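import numpy as np
import pytest
from sklearn.base import clone

from kinofit.fitter import (
    FitConfig,
    KineticCurveFit,
    coordinate_descent,
    fit_all_models,
    fit_series,
    sse,
)
from kinofit.models import KinomicSeries, eval_model, initial_params

from conftest import make_series


class TestSse:
    def test_perfect_fit_is_zero(self, noiseless_eq3_series, eq3_truth):
        assert sse(noiseless_eq3_series, "eq3", eq3_truth) == 0.0

    def test_hand_residuals(self):
        # engineer residuals (1, -2, 3) around an eq3 curve
        c = np.array([5.0, 10.0, 15.0])
        params = (100.0, 2.0, 0.0)
        y = np.asarray(eval_model("eq3", params, c)) - np.array([1.0, -2.0, 3.0])
        series = KinomicSeries("p", "s", c, y)
        assert sse(series, "eq3", params) == pytest.approx(14.0)

    def test_single_point(self):
        c = np.array([10.0])
        y = np.asarray(eval_model("eq3", (100.0, 2.0, 0.0), c)) - 2.5
        series = KinomicSeries("p", "s", c, y)
        assert sse(series, "eq3", (100.0, 2.0, 0.0)) == pytest.approx(2.5**2)


class TestCoordinateDescent:
    def test_noiseless_eq3_recovery(self, noiseless_eq3_series):
        result = fit_series(noiseless_eq3_series, "eq3")
        assert result.params["vi"] == pytest.approx(2.0, rel=0.01)
        assert result.sse < 1e-6 * np.sum(noiseless_eq3_series.signals**2)

    def test_start_at_optimum_terminates_immediately(
        self, noiseless_eq3_series, eq3_truth
    ):
        result = fit_series(noiseless_eq3_series, "eq3", init=eq3_truth)
        assert result.converged_by == "SSE_CHANGE"
        assert result.sse == 0.0
        np.testing.assert_array_equal(result.param_vector, eq3_truth)

    def test_final_sse_never_exceeds_initial(self, cycles13):
        rng = np.random.default_rng(3)
        series = make_series("eq3", (300.0, 5.0, 1.0), cycles13,
                             noise_sd=10.0, rng=rng)
        init = initial_params("eq3", series)
        result = fit_series(series, "eq3", init=init)
        assert result.sse <= sse(series, "eq3", init.values)

    def test_line_fit_matches_grid_search_oracle(self):
        rng = np.random.default_rng(7)
        c = np.arange(1.0, 14.0)
        y = 3.0 + 2.0 * c + rng.normal(0, 1.0, c.size)

        def line(p, x):
            return p[0] + p[1] * x

        p, fitted_sse, _, _ = coordinate_descent(
            line, c, y, np.array([1.0, 1.0]), FitConfig()
        )
        a = np.linspace(-5, 10, 200)
        b = np.linspace(-2, 6, 200)
        grid_sse = np.min(
            np.sum(
                (a[:, None, None] + b[None, :, None] * c[None, None, :]
                 - y[None, None, :]) ** 2,
                axis=2,
            )
        )
        assert fitted_sse <= 1.01 * grid_sse

    def test_invalid_start_rejected(self, noiseless_eq3_series):
        with pytest.raises(ValueError, match="invalid start"):
            fit_series(noiseless_eq3_series, "eq3",
                       init=np.array([np.nan, 1.0, 0.0]))

    def test_deterministic(self, cycles13):
        rng = np.random.default_rng(5)
        series = make_series("eq3", (300.0, 5.0, 1.0), cycles13,
                             noise_sd=10.0, rng=rng)
        r1 = fit_series(series, "eq3")
        r2 = fit_series(series, "eq3")
        np.testing.assert_array_equal(r1.param_vector, r2.param_vector)
        assert r1.sse == r2.sse
        assert r1.iterations_used == r2.iterations_used

    @pytest.mark.parametrize("model", ["eq2", "eq3"])
    def test_signal_scaling_equivariance(self, cycles13, model):
        """Scaling all signals by s scales the y-dimension parameters
        (y0, ymax, vi) by s and leaves k, c0 unchanged."""
        params = {"eq2": (2.0, 300.0, 0.05, 1.0), "eq3": (300.0, 5.0, 1.0)}[model]
        base = make_series(model, params, cycles13)
        scaled = KinomicSeries("p", "s", cycles13, 10.0 * base.signals)
        r1 = fit_series(base, model)
        r2 = fit_series(scaled, model)
        y_dim = {"y0", "ymax", "vi"}
        for name, value in r1.params.items():
            factor = 10.0 if name in y_dim else 1.0
            assert r2.params[name] == pytest.approx(factor * value, rel=1e-3)

    def test_jit_and_python_engines_agree(self, cycles13):
        rng = np.random.default_rng(11)
        series = make_series("eq3", (400.0, 6.0, 2.0), cycles13,
                             noise_sd=5.0, rng=rng)
        init = initial_params("eq3", series)
        jit = fit_series(series, "eq3", init=init)

        def eq3(p, x):
            num = p[1] * (x - p[2])
            return p[0] * num / (p[0] + num)

        p_py, sse_py, it_py, _ = coordinate_descent(
            eq3, series.cycles, series.signals, init.values, FitConfig()
        )
        np.testing.assert_allclose(jit.param_vector, p_py, rtol=1e-9)
        assert jit.sse == pytest.approx(sse_py, rel=1e-9)
        assert jit.iterations_used == it_py


class TestFitAllModels:
    def test_three_entries_for_13_points(self, cycles13):
        rng = np.random.default_rng(2)
        series = make_series("eq3", (300.0, 5.0, 1.0), cycles13,
                             noise_sd=8.0, rng=rng)
        fits = fit_all_models(series)
        assert set(fits) == {"eq1", "eq2", "eq3"}

    def test_noiseless_eq2_data_fit_by_eq2(self, cycles13):
        series = make_series("eq2", (5.0, 200.0, 0.08, 1.0), cycles13)
        fits = fit_all_models(series)
        assert fits["eq2"].sse < 1e-6 * np.sum(series.signals**2)

    def test_short_series_drops_models_needing_more_points(self):
        # 4 points: eq1/eq3 (3 params) fit, eq2 (4 params) is absent
        c = np.array([1.0, 5.0, 9.0, 13.0])
        y = np.asarray(eval_model("eq3", (100.0, 2.0, 0.0), c))
        fits = fit_all_models(KinomicSeries("p", "s", c, y))
        assert "eq2" not in fits
        assert {"eq1", "eq3"} <= set(fits)

    def test_flat_series_degenerate_not_raised(self, cycles13):
        series = KinomicSeries("p", "s", cycles13, np.zeros(13))
        fits = fit_all_models(series)
        assert all(f.degenerate for f in fits.values())


class TestFitConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"max_iterations": 0},
            {"initial_step_fraction": 0.0},
            {"min_sse_percent_change": 0.0},
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FitConfig(**kwargs)

    def test_zero_start_gets_absolute_step(self, cycles13):
        # c0 starting at 0 must still move: fit data whose true c0 != 0
        c = cycles13 + 2.0
        y = np.asarray(eval_model("eq3", (200.0, 4.0, 2.0), c))
        series = KinomicSeries("p", "s", c, y)
        result = fit_series(series, "eq3",
                            init=np.array([150.0, 3.0, 0.0]))
        assert result.params["c0"] != 0.0


class TestKineticCurveFitEstimator:
    def test_fit_predict_roundtrip(self, cycles13, noiseless_eq3_series):
        est = KineticCurveFit(model="eq3").fit(
            cycles13, noiseless_eq3_series.signals
        )
        assert est.params_["vi"] == pytest.approx(2.0, rel=0.01)
        pred = est.predict(cycles13)
        assert np.max(np.abs(pred - noiseless_eq3_series.signals)) < 0.5
        assert est.r_squared_ > 0.999
        assert est.converged_by_ in ("SSE_CHANGE", "MAX_ITER")
        assert est.n_iter_ <= est.max_iterations

    def test_accepts_column_vector_X(self, cycles13, noiseless_eq3_series):
        est = KineticCurveFit().fit(
            cycles13.reshape(-1, 1), noiseless_eq3_series.signals
        )
        assert est.predict(cycles13.reshape(-1, 1)).shape == (13,)

    def test_sklearn_clone_and_get_params(self):
        est = KineticCurveFit(model="eq1", max_iterations=50)
        cloned = clone(est)
        assert cloned.get_params()["model"] == "eq1"
        assert cloned.get_params()["max_iterations"] == 50

    def test_predict_before_fit_raises(self, cycles13):
        with pytest.raises(AttributeError):
            KineticCurveFit().predict(cycles13)
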