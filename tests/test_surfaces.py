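"""Response-surface fits, prediction sanitization, light-response traits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from daphnegain import (HybridResponseSurface, LorentzianParams,
                        ParaboloidParams, fit_light_response, fit_lorentzian,
                        fit_paraboloid, nonrectangular_hyperbola,
                        sanitize_predictions)
from daphnegain.surfaces import (ParaboloidSurfaceRegressor,
                                 _r2_corrected)
from daphnegain.synthetic import DEFAULT_TEMPS

LOW_PARS = (0.0, 10.0, 30.0, 50.0)
HIGH_PARS = (100.0, 300.0, 500.0, 700.0, 900.0, 1100.0)

TRUE_LOW = ParaboloidParams(k=1.2, a=0.03, b=0.05, c=-0.002, d=1e-4)
TRUE_HIGH = LorentzianParams(a=8.0, k=20.0, b=15.0, l=900.0, c=800.0)


def _grid_frame(params, pars, noise_sd=0.0, seed=0):
    tt, pp = np.meshgrid(DEFAULT_TEMPS, pars, indexing="ij")
    tt, pp = tt.ravel(), pp.ravel()
    pn = params.predict(tt, pp)
    if noise_sd:
        pn = pn + np.random.default_rng(seed).normal(0.0, noise_sd, pn.size)
    return pd.DataFrame({"temp": tt, "par": pp, "pn": pn})


class TestParaboloidFit:
    def test_noiseless_grid_recovers_parameters(self):
        data = _grid_frame(TRUE_LOW, LOW_PARS)
        fitted, diag = fit_paraboloid(data)
        for name in ("k", "a", "b", "c", "d"):
            assert getattr(fitted, name) == pytest.approx(
                getattr(TRUE_LOW, name), abs=1e-6)
        assert diag["r2"] == pytest.approx(1.0, abs=1e-12)

    def test_noisy_fit_within_3se_and_r2_matches_hand_calculation(self):
        data = _grid_frame(TRUE_LOW, LOW_PARS, noise_sd=0.1, seed=11)
        fitted, diag = fit_paraboloid(data)
        # independent SE oracle: sigma^2 (X'X)^-1 from the design matrix
        t, p, y = (data[c].to_numpy() for c in ("temp", "par", "pn"))
        X = np.column_stack([np.ones_like(t), t, p, t**2, p**2])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (len(y) - 5)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
        truth = np.array([TRUE_LOW.k, -TRUE_LOW.a, TRUE_LOW.b, TRUE_LOW.c,
                          -TRUE_LOW.d])
        assert np.all(np.abs(beta - truth) <= 3 * se)
        sse = float(resid @ resid)
        sst = float(np.sum((y - y.mean()) ** 2))
        assert diag["r2"] == pytest.approx(1 - sse / sst, abs=1e-10)
        assert diag["n"] == 24  # six temperatures x four low-light PAR levels

    def test_rank_deficient_design_rejected(self):
        data = pd.DataFrame({"temp": [5.0, 10, 15, 20, 25, 30],
                             "par": [10.0] * 6,
                             "pn": np.linspace(0, 2, 6)})
        with pytest.raises(ValueError):
            fit_paraboloid(data)

    def test_fit_quality_within_reported_envelope(self, ref_surface):
        from daphnegain import fit_hybrid_surface, generate_response_measurements
        data = generate_response_measurements(ref_surface, noise_sd=0.4, seed=3)
        surf = fit_hybrid_surface(data, random_state=3)
        for r2 in (surf.fit_r2_low, surf.fit_r2_high):
            assert 0.52 <= r2 <= 0.97


class TestLorentzianFit:
    def test_noiseless_grid_recovers_parameters(self):
        data = _grid_frame(TRUE_HIGH, HIGH_PARS)
        fitted, diag = fit_lorentzian(data)
        for name in ("a", "k", "b", "l", "c"):
            assert getattr(fitted, name) == pytest.approx(
                getattr(TRUE_HIGH, name), abs=1e-4)
        assert diag["converged"]

    def test_noisy_fit_predictions_close_to_generating_surface(self):
        sd = 0.1
        data = _grid_frame(TRUE_HIGH, HIGH_PARS, noise_sd=sd, seed=4)
        fitted, _ = fit_lorentzian(data)
        tt, pp = data["temp"].to_numpy(), data["par"].to_numpy()
        rms = np.sqrt(np.mean((fitted.predict(tt, pp)
                               - TRUE_HIGH.predict(tt, pp)) ** 2))
        assert rms <= 2 * sd

    def test_surface_peak_at_joint_optimum(self):
        data = _grid_frame(TRUE_HIGH, HIGH_PARS, noise_sd=0.05, seed=5)
        fitted, _ = fit_lorentzian(data)
        assert fitted.predict(fitted.k, fitted.l) == pytest.approx(fitted.a)

    @settings(derandomize=True, max_examples=50)
    @given(temp=st.floats(-50, 80), par=st.floats(0, 3000))
    def test_lorentzian_prediction_bounded_by_peak(self, temp, par):
        assert abs(TRUE_HIGH.predict(temp, par)) <= abs(TRUE_HIGH.a) + 1e-12

    def test_degenerate_data_rejected(self):
        data = pd.DataFrame({"temp": [5.0, 10, 15] * 3,
                             "par": [100.0] * 3 + [300.0] * 3 + [500.0] * 3,
                             "pn": [2.0] * 9})
        with pytest.raises(ValueError, match="degenerate"):
            fit_lorentzian(data)


class TestHybridPrediction:
    def test_low_regime_hand_evaluation(self):
        low = ParaboloidParams(k=1.0, a=0.1, b=0.05, c=0.001, d=0.0001)
        assert low.predict(20.0, 0.0) == pytest.approx(-0.6)

    def test_split_boundary_belongs_to_high_regime(self):
        surf = HybridResponseSurface(
            low=ParaboloidParams(k=100.0, a=0, b=0, c=0, d=0),
            high=TRUE_HIGH)
        at_split = float(surf.predict(TRUE_HIGH.k, surf.par_split))
        assert at_split == pytest.approx(
            TRUE_HIGH.predict(TRUE_HIGH.k, surf.par_split))
        below = float(surf.predict(TRUE_HIGH.k, surf.par_split - 1e-9))
        assert below == pytest.approx(100.0)

    def test_prediction_at_joint_optimum_equals_peak(self):
        surf = HybridResponseSurface(low=TRUE_LOW, high=TRUE_HIGH)
        assert float(surf.predict(TRUE_HIGH.k, TRUE_HIGH.l)) == pytest.approx(8.0)


class TestSanitization:
    def test_dark_positive_replaced_by_flanking_dark_values(self):
        temp = np.full(3, 15.0)
        par = np.zeros(3)
        pn = np.array([-0.5, 0.4, -0.5])
        clean, n = sanitize_predictions(temp, par, pn)
        assert n == 1
        np.testing.assert_allclose(clean, [-0.5, -0.5, -0.5])

    def test_consistent_series_returned_unchanged(self):
        temp = np.full(5, 15.0)
        par = np.array([0.0, 50, 100, 50, 0])
        pn = np.array([-0.5, 1.0, 2.0, 1.0, -0.5])
        clean, n = sanitize_predictions(temp, par, pn)
        assert n == 0
        np.testing.assert_array_equal(clean, pn)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_dark_predictions_nonpositive_after_sanitization(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        par = np.where(rng.random(n) < 0.5, 0.0, rng.uniform(10, 200, n))
        temp = np.full(n, 20.0)
        pn = rng.normal(0.0, 1.0, n)
        if not (((par <= 0) & (pn <= 0)) | ((par > 0) & (pn >= -10))).any():
            return
        try:
            clean, _ = sanitize_predictions(temp, par, pn)
        except ValueError:
            return  # everything flagged: legitimate abort
        assert (clean[par <= 0] <= 0).all()

    def test_all_flagged_aborts(self):
        with pytest.raises(ValueError, match="all predictions flagged"):
            sanitize_predictions(np.full(3, 20.0), np.zeros(3),
                                 np.array([1.0, 2.0, 3.0]))


class TestLightResponse:
    def test_noiseless_recovery_and_bisection_lcp_oracle(self):
        par = np.array([0, 10, 30, 50, 100, 300, 500, 700, 900, 1100], float)
        truth = (0.05, 0.7, 10.0, 0.6)
        pn = nonrectangular_hyperbola(par, *truth)
        traits = fit_light_response(par, pn)
        assert (traits.phi, traits.theta, traits.pmax, traits.rd) == pytest.approx(
            truth, abs=1e-4)
        assert traits.amax == pytest.approx(10.0 - 0.6, abs=1e-4)
        lcp_oracle = optimize.bisect(
            lambda q: nonrectangular_hyperbola(q, *truth), 1e-9, 500, xtol=1e-10)
        assert traits.lcp == pytest.approx(lcp_oracle, abs=1e-4)

    def test_recovered_rd_equals_negative_dark_pn(self):
        par = np.array([0, 10, 30, 50, 100, 300, 500, 700, 900, 1100], float)
        pn = nonrectangular_hyperbola(par, 0.05, 0.7, 10.0, 0.6)
        traits = fit_light_response(par, pn)
        assert traits.rd == pytest.approx(-pn[0], abs=1e-6)

    def test_flat_curve_rejected(self):
        par = np.array([0.0, 50, 300, 900])
        with pytest.raises(ValueError, match="degenerate"):
            fit_light_response(par, np.zeros(4))

    def test_curve_without_dark_point_rejected(self):
        par = np.array([100.0, 300, 500, 900])
        with pytest.raises(ValueError, match="dark"):
            fit_light_response(par, np.array([1.0, 2, 2.5, 2.6]))
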