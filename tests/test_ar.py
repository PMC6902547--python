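import math

import numpy as np
import pytest

from stridestab.ar import (
    CENTROID,
    TRIANGLE_VERTICES,
    ar_distance,
    characteristic_roots,
    classify_stability,
    correlogram,
    fit_ar2,
    is_stationary,
    triangle_geometry,
)
from stridestab.errors import DegenerateFitError, ParameterError, ShortSeriesError
from stridestab.synthetic import simulate_subject

from conftest import make_detrended


def independent_ols_ar2(y):
    """Independent oracle: AR(2) CLS via explicit normal equations."""
    y = np.asarray(y, dtype=float)
    n = y.size
    X = np.column_stack([np.ones(n - 2), y[1:-1], y[:-2]])
    beta = np.linalg.solve(X.T @ X, X.T @ y[2:])
    return beta[1], beta[2]  # phi1, phi2


class TestFitAr2:
    def test_exact_ar2_recursion_recovered_to_machine_precision(self):
        # noise-free AR(2) recursion with generic initial conditions: the two
        # lagged regressors are independent, so CLS is exact
        phi1, phi2 = 0.5, -0.3
        y = np.zeros(100)
        y[0], y[1] = 1.0, 0.3
        for t in range(2, 100):
            y[t] = phi1 * y[t - 1] + phi2 * y[t - 2]
        fit = fit_ar2(make_detrended(y))
        assert fit.phi1 == pytest.approx(phi1, abs=1e-10)
        assert fit.phi2 == pytest.approx(phi2, abs=1e-10)
        assert fit.delta == pytest.approx(0.0, abs=1e-12)
        assert fit.n_effective == 98

    def test_pure_ar1_decay_is_degenerate(self):
        # y_t = 0.5 y_{t-1} exactly makes the lagged columns collinear
        # (y_{t-1} = 0.5 y_{t-2}), so no unique AR(2) fit exists
        y = 0.5 ** np.arange(100.0)
        with pytest.raises(DegenerateFitError):
            fit_ar2(make_detrended(y))

    def test_white_noise_coefficients_near_zero(self, rng):
        n = 100_000
        y = rng.normal(0.0, 0.05, size=n)
        fit = fit_ar2(make_detrended(y))
        assert abs(fit.phi1) < 3 / math.sqrt(n)
        assert abs(fit.phi2) < 3 / math.sqrt(n)

    def test_cls_matches_independent_ols_oracle(self, rng):
        s = simulate_subject(0.4, 0.1, 1.1, 0.05, 0.0, 300, seed=42)
        y = s.stride_times - s.stride_times.mean()
        fit = fit_ar2(make_detrended(y), method="cls")
        phi1_o, phi2_o = independent_ols_ar2(y)
        assert fit.phi1 == pytest.approx(phi1_o, abs=1e-10)
        assert fit.phi2 == pytest.approx(phi2_o, abs=1e-10)

    def test_monte_carlo_recovery_table2_control_values(self):
        # generative truth (0.4, 0.1); mild negative finite-sample bias expected
        reps, n = 500, 300
        est = np.empty((reps, 2))
        for r in range(reps):
            s = simulate_subject(0.4, 0.1, 1.1, 0.05, 0.0, n, seed=9000 + r)
            fit = fit_ar2(make_detrended(s.stride_times - s.stride_times.mean()))
            est[r] = fit.phi1, fit.phi2
        m1, m2 = est.mean(axis=0)
        assert 0.35 <= m1 <= 0.42
        assert 0.05 <= m2 <= 0.12

    def test_constant_residuals_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_ar2(make_detrended(np.zeros(100)))
        with pytest.raises(DegenerateFitError):
            fit_ar2(make_detrended(np.zeros(100)), method="yule_walker")

    def test_short_series(self):
        with pytest.raises(ShortSeriesError):
            fit_ar2(make_detrended(np.random.default_rng(0).normal(size=29)))

    def test_unknown_method(self):
        with pytest.raises(ParameterError):
            fit_ar2(make_detrended(np.random.default_rng(0).normal(size=50)), method="mle")

    def test_yule_walker_close_to_cls_for_long_series(self):
        s = simulate_subject(0.4, 0.1, 1.1, 0.05, 0.0, 5000, seed=7)
        y = s.stride_times - s.stride_times.mean()
        cls = fit_ar2(make_detrended(y), method="cls")
        yw = fit_ar2(make_detrended(y), method="yule_walker")
        assert abs(cls.phi1 - yw.phi1) < 0.02
        assert abs(cls.phi2 - yw.phi2) < 0.02
        assert yw.sigma2 == pytest.approx(cls.sigma2, rel=0.1)

    def test_sigma2_estimates_innovation_variance(self):
        sd = 0.05
        s = simulate_subject(0.4, 0.1, 1.1, sd, 0.0, 20_000, seed=3)
        fit = fit_ar2(make_detrended(s.stride_times - s.stride_times.mean()))
        assert fit.sigma2 == pytest.approx(sd**2, rel=0.05)


class TestCorrelogram:
    def test_lag_zero_is_one(self, rng):
        c = correlogram(make_detrended(rng.normal(size=200)), max_lag=10)
        assert c.acf[0] == 1.0
        assert c.pacf[0] == 1.0
        assert c.ci_halfwidth == pytest.approx(1.96 / math.sqrt(200))

    def test_noiseless_half_decay_acf(self):
        # analytic AR(1) ACF oracle: rho(k) = 0.5^k
        y = 0.5 ** np.arange(100.0)
        c = correlogram(make_detrended(y), max_lag=3)
        for k in range(1, 4):
            assert c.acf[k] == pytest.approx(0.5**k, abs=0.01)

    def test_white_noise_acf_within_band(self, rng):
        # null distribution: in most replicates all 20 lags stay inside 3x band
        hits = 0
        reps = 40
        for _ in range(reps):
            c = correlogram(make_detrended(rng.normal(size=10_000)), max_lag=20)
            if np.all(np.abs(c.acf[1:]) < 3 * c.ci_halfwidth):
                hits += 1
        assert hits / reps >= 0.95

    def test_pacf_matches_statsmodels(self, rng):
        from statsmodels.tsa.stattools import acf as sm_acf, pacf as sm_pacf

        y = rng.normal(size=500)
        c = correlogram(make_detrended(y), max_lag=10)
        np.testing.assert_allclose(c.acf, sm_acf(y, nlags=10, adjusted=False), atol=1e-10)
        np.testing.assert_allclose(c.pacf, sm_pacf(y, nlags=10, method="ldb"), atol=1e-8)

    def test_ar2_pacf_cuts_off_after_lag_two(self):
        s = simulate_subject(0.4, 0.1, 1.1, 0.05, 0.0, 10_000, seed=11)
        c = correlogram(make_detrended(s.stride_times - s.stride_times.mean()), max_lag=10)
        assert abs(c.pacf[1]) > 3 * c.ci_halfwidth
        assert abs(c.pacf[2]) > 3 * c.ci_halfwidth
        assert np.all(np.abs(c.pacf[3:]) < 4 * c.ci_halfwidth)

    def test_max_lag_bound(self, rng):
        with pytest.raises(ParameterError):
            correlogram(make_detrended(rng.normal(size=40)), max_lag=20)


class TestClassify:
    def test_centroid_is_oscillatory(self):
        a = classify_stability(0.0, -1.0 / 3.0)
        assert a.region == "oscillatory"
        assert a.distance == 0.0

    def test_table2_control_mean_is_non_oscillatory(self):
        a = classify_stability(0.4, 0.1)
        assert a.region == "non_oscillatory"

    def test_outside_triangle_is_unstable(self):
        assert classify_stability(1.5, 0.5).region == "unstable"

    def test_origin_is_discriminant_boundary(self):
        a = classify_stability(0.0, 0.0)
        assert a.region == "boundary"
        assert is_stationary(0.0, 0.0)

    def test_triangle_edge_is_boundary(self):
        assert classify_stability(0.5, 0.5).region == "boundary"  # phi1+phi2 = 1

    def test_roots_consistent_with_region(self):
        osc = classify_stability(0.1, -0.5)
        assert osc.region == "oscillatory"
        assert all(abs(r.imag) > 0 for r in osc.char_roots)
        non = classify_stability(0.4, 0.1)
        assert all(r.imag == 0 for r in non.char_roots)
        assert all(abs(r) < 1 for r in non.char_roots)
        uns = classify_stability(1.5, 0.5)
        assert max(abs(r) for r in uns.char_roots) > 1

    def test_invalid_tol(self):
        with pytest.raises(ParameterError):
            classify_stability(0.0, 0.0, tol=0.0)

    def test_grid_equivalence_with_root_criterion(self):
        # 101x101 fast version of the acceptance-grade grid check
        grid = np.linspace(-2.5, 2.5, 101)
        for phi1 in grid:
            for phi2 in grid:
                a = classify_stability(phi1, phi2)
                if a.region == "boundary":
                    continue
                max_mod = max(abs(r) for r in characteristic_roots(phi1, phi2))
                assert (a.region != "unstable") == (max_mod < 1), (phi1, phi2)


class TestDistanceAndGeometry:
    def test_distance_examples(self):
        assert ar_distance(0.0, -1.0 / 3.0) == 0.0
        assert ar_distance(0.0, 1.0) == pytest.approx(4.0 / 3.0, abs=1e-12)
        # hand Euclidean oracle for the Table-2 control mean pair
        assert ar_distance(0.4, 0.1) == pytest.approx(
            math.sqrt(0.4**2 + (0.1 + 1.0 / 3.0) ** 2), abs=1e-12
        )
        assert ar_distance(0.4, 0.1) == pytest.approx(0.5897268670984711, abs=1e-12)

    def test_centroid_is_vertex_average(self):
        vertices, centroid = triangle_geometry()
        assert centroid == (0.0, -1.0 / 3.0)
        np.testing.assert_allclose(np.mean(vertices, axis=0), centroid, atol=1e-15)

    def test_vertex_satisfies_two_constraints_with_equality(self):
        phi1, phi2 = 2.0, -1.0
        assert phi1 + phi2 == 1.0  # boundary of phi1 + phi2 < 1
        assert abs(phi2) == 1.0  # boundary of |phi2| < 1

    def test_triangle_area_shoelace(self):
        (x1, y1), (x2, y2), (x3, y3) = TRIANGLE_VERTICES
        area = 0.5 * abs(x1 * (y2 - y3) + x2 * (y3 - y1) + x3 * (y1 - y2))
        assert area == pytest.approx(4.0, abs=1e-12)

    def test_centroid_constant(self):
        assert CENTROID == (0.0, -1.0 / 3.0)
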