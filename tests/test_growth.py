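"""Sigmoid growth fitting, rates and regional summaries."""

import math

import numpy as np
import pytest

from skinstrain.growth import (
    GrowthSeries,
    InsufficientDataError,
    NotConvergedError,
    SigmoidFit,
    fit_sigmoid,
    gompertz,
    growth_rate,
    logistic,
    max_growth_rate,
    regional_growth_summary,
)

T = np.arange(40.0, 161.0, 5.0)
TRUE = dict(a_max=400.0, k=0.06, t_mid=95.0)


def make_series(model=logistic, cultivar="cv", region="whole", **params):
    p = {**TRUE, **params}
    return GrowthSeries(cultivar, T, model(T, p["a_max"], p["k"], p["t_mid"]), region)


class TestFit:
    def test_noiseless_logistic_recovery(self):
        fit = fit_sigmoid(make_series())
        assert fit.converged
        assert fit.a_max == pytest.approx(TRUE["a_max"], rel=1e-6)
        assert fit.k == pytest.approx(TRUE["k"], rel=1e-6)
        assert fit.t_mid == pytest.approx(TRUE["t_mid"], rel=1e-6)

    def test_noiseless_gompertz_recovery(self):
        fit = fit_sigmoid(make_series(model=gompertz), model="gompertz")
        assert fit.converged
        assert fit.a_max == pytest.approx(TRUE["a_max"], rel=1e-5)
        assert fit.k == pytest.approx(TRUE["k"], rel=1e-5)

    def test_deterministic_refit(self):
        s = make_series()
        f1, f2 = fit_sigmoid(s), fit_sigmoid(s)
        assert (f1.a_max, f1.k, f1.t_mid) == (f2.a_max, f2.k, f2.t_mid)

    def test_constant_series_flagged_not_raised(self):
        s = GrowthSeries("cv", T, np.full_like(T, 50.0))
        fit = fit_sigmoid(s)
        assert (not fit.converged) or fit.k < 1e-6

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_sigmoid(GrowthSeries("cv", T[:3], logistic(T[:3], 400, 0.06, 95)))

    def test_series_validation(self):
        with pytest.raises(ValueError):
            GrowthSeries("cv", [1.0, 1.0, 2.0, 3.0], [1, 2, 3, 4])
        with pytest.raises(ValueError):
            GrowthSeries("cv", [1.0, 2.0, 3.0, 4.0], [1, -2, 3, 4])

    def test_unknown_model(self):
        with pytest.raises(ValueError):
            fit_sigmoid(make_series(), model="richards")


class TestRates:
    def test_logistic_rate_at_inflection(self):
        fit = fit_sigmoid(make_series())
        assert growth_rate(fit, fit.t_mid) == pytest.approx(400 * 0.06 / 4, rel=1e-6)

    def test_rate_vanishes_far_in_the_past(self):
        fit = fit_sigmoid(make_series())
        assert growth_rate(fit, -1e4) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("model", ["logistic", "gompertz"])
    def test_analytic_matches_central_difference(self, model):
        func = logistic if model == "logistic" else gompertz
        fit = fit_sigmoid(make_series(model=func), model=model)
        h = 1e-5
        for t in (60.0, 95.0, 130.0):
            numeric = (fit.predict(t + h) - fit.predict(t - h)) / (2 * h)
            assert growth_rate(fit, t) == pytest.approx(numeric, rel=1e-6)

    def test_max_rate_logistic_closed_form(self):
        fit = fit_sigmoid(make_series())
        rate, t_at = max_growth_rate(fit)
        assert rate == pytest.approx(6.0, rel=1e-6)
        assert t_at == pytest.approx(95.0, rel=1e-6)

    def test_max_rate_gompertz_closed_form(self):
        fit = fit_sigmoid(make_series(model=gompertz), model="gompertz")
        rate, t_at = max_growth_rate(fit)
        assert rate == pytest.approx(400 * 0.06 / math.e, rel=1e-5)
        assert t_at == pytest.approx(95.0, rel=1e-4)

    @pytest.mark.parametrize("model", ["logistic", "gompertz"])
    def test_max_rate_matches_dense_grid_argmax(self, model):
        func = logistic if model == "logistic" else gompertz
        fit = fit_sigmoid(make_series(model=func), model=model)
        grid = np.arange(40.0, 160.0, 0.01)
        rates = growth_rate(fit, grid)
        rate, t_at = max_growth_rate(fit)
        assert rate >= rates.max() - 1e-9
        assert abs(t_at - grid[np.argmax(rates)]) <= 0.01

    def test_rate_requires_convergence(self):
        bad = SigmoidFit("logistic", 1.0, 0.1, 50.0, float("nan"), converged=False)
        with pytest.raises(NotConvergedError):
            max_growth_rate(bad)

    def test_fitted_curve_monotone_over_data_range(self):
        fit = fit_sigmoid(make_series())
        pred = fit.predict(np.arange(40.0, 160.0, 0.5))
        assert np.all(np.diff(pred) >= 0)


class TestRegionalSummary:
    def test_identical_series_give_identical_fits(self):
        rows = regional_growth_summary(
            [make_series(region=r) for r in ("apex", "cheek", "back")]
        )
        rates = {row.max_rate for row in rows}
        assert len(rates) == 1

    def test_area_scale_leaves_relative_rate_unchanged(self):
        rows = regional_growth_summary(
            [make_series(region="apex"), make_series(region="cheek", a_max=800.0)]
        )
        rel = [row.relative_rate_at_max for row in rows]
        assert rel[0] == pytest.approx(rel[1], rel=1e-6)
        assert rows[0].max_rate * 2 == pytest.approx(rows[1].max_rate, rel=1e-6)

    def test_distinct_k_recovered_in_rank_order(self):
        ks = [0.04, 0.055, 0.07]
        rows = regional_growth_summary(
            [make_series(region=r, k=k) for r, k in zip(("apex", "cheek", "back"), ks)]
        )
        fitted = [row.fit.k for row in rows]
        assert fitted == sorted(fitted)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            regional_growth_summary([])

    def test_failed_fits_reported_not_dropped(self):
        flat = GrowthSeries("cv", T, np.full_like(T, 50.0), "nak")
        rows = regional_growth_summary([make_series(region="apex"), flat])
        assert len(rows) == 2
        flagged = {row.region: row.failed for row in rows}
        assert not flagged["apex"]
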