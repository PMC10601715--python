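"""Dose-response cascade: linear/WLS fits, GAM, AIC selection, broken stick."""

import math
import warnings

import numpy as np
import pytest

from plastmeta.dose import (
    PiecewiseRegression,
    fit_gam,
    fit_linear,
    fit_segmented,
    grid_search_breakpoint,
    select_model,
    zero_crossing,
)
from plastmeta.records import ModelFit


def broken_stick(x, b0, b1, b2, c):
    return b0 + b1 * x + b2 * np.clip(x - c, 0, None)


class TestLinear:
    def test_exact_fit_no_noise(self):
        x = np.linspace(0, 5, 20)
        y = 2 + 3 * x
        f = fit_linear(x, y)
        assert f.beta0 == pytest.approx(2.0, abs=1e-10)
        assert f.beta1 == pytest.approx(3.0, abs=1e-10)
        assert f.residual_se == pytest.approx(0.0, abs=1e-8)
        assert f.r2 == pytest.approx(1.0)

    def test_equal_weights_match_unweighted(self, rng):
        x = rng.uniform(0, 10, 50)
        y = 1 + 0.5 * x + rng.normal(0, 0.3, 50)
        f1 = fit_linear(x, y)
        f2 = fit_linear(x, y, weights=np.full(50, 7.0))
        assert f2.beta0 == pytest.approx(f1.beta0, abs=1e-10)
        assert f2.beta1 == pytest.approx(f1.beta1, abs=1e-10)

    def test_slope_recovery_with_noise(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 10, 200)
        y = x + rng.normal(0, 0.1, 200)
        f = fit_linear(x, y)
        assert 0.97 < f.beta1 < 1.03
        assert f.p_model < 1e-10

    def test_constant_x_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            fit_linear(np.ones(10), np.arange(10.0))


class TestGam:
    def test_linear_limit(self, rng):
        x = np.linspace(0, 10, 100)
        y = 1 + 0.3 * x + rng.normal(0, 0.1, 100)
        g = fit_gam(x, y)
        lin = fit_linear(x, y)
        assert np.max(np.abs(g.predict(x) - lin.predict(x))) < 2 * lin.residual_se
        # AIC rule must not prefer the smooth on straight-line data
        assert select_model([lin, g]).model_kind == "ols"

    def test_detects_sine_nonlinearity(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 2 * math.pi, 300)
        y = np.sin(x) + rng.normal(0, 0.2, 300)
        g = fit_gam(x, y)
        lin = fit_linear(x, y)
        assert g.aic < lin.aic - 2

    def test_constant_response_flat_fit(self):
        x = np.linspace(0, 1, 50)
        y = np.full(50, 2.5)
        g = fit_gam(x, y)
        assert np.allclose(g.predict(x), 2.5, atol=1e-6)

    def test_small_n_reduces_basis_with_warning(self, rng):
        x = np.linspace(0, 1, 12)
        y = rng.normal(size=12)
        with pytest.warns(UserWarning, match="reduced"):
            fit_gam(x, y, df=10)


class TestSelectModel:
    @pytest.mark.parametrize(
        "aic_gam,aic_ols,winner",
        [(100.0, 103.0, "gam"), (100.0, 101.0, "ols"), (100.0, 100.0, "ols"),
         (100.0, 102.0, "gam"), (100.0, 101.9999, "ols")],
    )
    def test_two_unit_rule_on_constructed_pairs(self, aic_gam, aic_ols, winner):
        gam = ModelFit(model_kind="gam", aic=aic_gam, n=50)
        ols = ModelFit(model_kind="ols", aic=aic_ols, n=50)
        assert select_model([ols, gam]).model_kind == winner

    def test_mismatched_data_rejected(self):
        gam = ModelFit(model_kind="gam", aic=1.0, n=50)
        ols = ModelFit(model_kind="ols", aic=5.0, n=60)
        with pytest.raises(ValueError, match="mismatched"):
            select_model([ols, gam])


class TestSegmented:
    def test_noise_free_exact_recovery(self):
        x = np.linspace(0.05, 20, 120)
        y = broken_stick(x, 1.0, 0.5, -0.7, 10.0)
        f = fit_segmented(x, y)
        assert f.model_kind == "segmented"
        assert f.breakpoint == pytest.approx(10.0, abs=1e-6)
        assert f.beta1 == pytest.approx(0.5, abs=1e-8)
        assert f.beta2 == pytest.approx(-0.7, abs=1e-8)
        assert f.slope_post == pytest.approx(-0.2, abs=1e-8)

    def test_linear_data_degenerates_to_linear_fit(self):
        x = np.linspace(0, 10, 40)
        y = 2 - 0.3 * x  # exactly linear: no breakpoint can improve
        with pytest.warns(UserWarning):
            f = fit_segmented(x, y)
        lin = fit_linear(x, y)
        assert f.breakpoint is None
        assert f.beta0 == pytest.approx(lin.beta0, abs=1e-8)
        assert f.beta1 == pytest.approx(lin.beta1, abs=1e-8)

    def test_prediction_continuous_at_breakpoint(self, rng):
        x = rng.uniform(0, 20, 150)
        y = broken_stick(x, 0.5, 0.3, -0.5, 8.0) + rng.normal(0, 0.05, 150)
        est = PiecewiseRegression().fit(x, y)
        c = est.breakpoint_
        eps = 1e-9
        below, above = est.predict([c - eps]), est.predict([c + eps])
        assert abs(float(above[0] - below[0])) < 1e-6

    def test_matches_grid_search_oracle_on_noisy_instances(self):
        mismatches = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            c_true = rng.uniform(5, 15)
            x = rng.uniform(0, 20, 120)
            y = broken_stick(x, rng.normal(), 0.4, -0.9, c_true) + rng.normal(0, 0.1, 120)
            est = PiecewiseRegression().fit(x, y)
            c_grid, _ = grid_search_breakpoint(x, y, n_grid=1000)
            step = np.ptp(x) / 1001
            if abs(est.breakpoint_ - c_grid) > step:
                mismatches += 1
        assert mismatches == 0

    def test_null_data_rarely_beats_linear_by_aic(self):
        # with no true break, the extra parameters shouldn't pay for themselves
        wins = 0
        for seed in range(200):
            rng = np.random.default_rng(1000 + seed)
            x = rng.uniform(0, 10, 60)
            y = 0.5 + 0.2 * x + rng.normal(0, 0.2, 60)
            lin = fit_linear(x, y)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                seg = fit_segmented(x, y)
            if seg.model_kind == "segmented" and seg.aic < lin.aic - 2:
                wins += 1
        assert wins <= 10  # <= 5% of 200

    def test_sklearn_interface(self, rng):
        x = rng.uniform(0, 20, 100)
        y = broken_stick(x, 0, 0.5, -1.0, 12.0) + rng.normal(0, 0.05, 100)
        est = PiecewiseRegression(tol=1e-10)
        est.fit(x[:, None], y)
        assert est.score(x[:, None], y) > 0.9
        params = est.get_params()
        assert params["tol"] == 1e-10
        clone = PiecewiseRegression(**params).fit(x, y)
        assert clone.breakpoint_ == pytest.approx(est.breakpoint_)


def test_selection_recovers_generating_model():
    """With the true model in the candidate set, AIC selection picks it in
    >= 90% of 200 simulations at n = 400 (broken-stick vs straight-line
    truths at the recovery signal-to-noise)."""
    correct = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        x = np.clip(np.exp(rng.normal(np.log(20), 1.0, 400)), 0.1, 100)
        y_nl = broken_stick(x, 0.0, 0.004, -0.005, 40.0) + rng.normal(0, 0.035, 400)
        y_l = 0.001 * x + rng.normal(0, 0.035, 400)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            correct += select_model([fit_linear(x, y_nl), fit_gam(x, y_nl)]).model_kind == "gam"
            correct += select_model([fit_linear(x, y_l), fit_gam(x, y_l)]).model_kind == "ols"
    assert correct >= 180


class TestZeroCrossing:
    def test_linear_closed_form(self):
        f = fit_linear(np.array([0.0, 4.0, 10.0]), np.array([1.0, -1.0, -4.0]))
        assert zero_crossing(f, (0, 10)) == pytest.approx(2.0, abs=1e-8)

    def test_no_crossing_returns_none(self):
        f = fit_linear(np.array([0.0, 5.0, 10.0]), np.array([1.0, 2.0, 3.0]))
        assert zero_crossing(f, (0, 10)) is None

    def test_segmented_root_recovered(self):
        # rises from -0.7 at 0, crosses zero at x = 3.5, breaks at 7
        x = np.linspace(0, 14, 200)
        y = broken_stick(x, -0.7, 0.2, -0.45, 7.0)
        f = fit_segmented(x, y)
        assert zero_crossing(f, (0, 14)) == pytest.approx(3.5, abs=1e-6)
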