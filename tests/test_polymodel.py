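import json

import numpy as np
import pytest
from scipy import stats

from merostab import QuadraticSurfaceRegressor, build_design_row, fit_ols
from merostab.dataset import PredictorStandardizer
from merostab.polymodel import SingularDesignError, TERM_NAMES, _design


def normal_equations_fit(X, y):
    """Brute-force oracle: explicit 6x6 normal-equations solve."""
    sc = PredictorStandardizer().fit(X)
    D = _design(sc.transform(X))
    return np.linalg.solve(D.T @ D, D.T @ y)


class TestDesignRow:
    @pytest.mark.parametrize(
        "x1,x2,expected",
        [
            (0, 0, [1, 0, 0, 0, 0, 0]),
            (1, -1, [1, 1, -1, 1, -1, 1]),
            (2, 3, [1, 2, 3, 4, 6, 9]),
        ],
    )
    def test_values(self, x1, x2, expected):
        np.testing.assert_array_equal(build_design_row(x1, x2), expected)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            build_design_row(np.nan, 0.0)


class TestFit:
    def test_matches_normal_equations_oracle(self, table1, fitted_model):
        oracle = normal_equations_fit(table1.predictors(), table1.response())
        np.testing.assert_allclose(fitted_model.coef_, oracle, atol=1e-10)

    def test_recovers_noise_free_quadratic_exactly(self, rng=np.random.default_rng(11)):
        truth = np.array([0.8, -0.15, -0.05, 0.01, -0.02, 0.02])
        X = np.column_stack([rng.uniform(0, 364, 60), rng.uniform(0.3, 90, 60)])
        sc = PredictorStandardizer().fit(X)
        y = _design(sc.transform(X)) @ truth
        model = QuadraticSurfaceRegressor().fit(X, y)
        np.testing.assert_allclose(model.predict(X), y, atol=1e-8)

    def test_degrees_of_freedom_and_f(self, fitted_model):
        assert fitted_model.df_residual_ == 133 - 6
        assert fitted_model.f_statistic_ >= 0
        cov = fitted_model.coef_covariance_
        np.testing.assert_allclose(cov, cov.T, atol=1e-18)
        assert np.all(np.linalg.eigvalsh(cov) > -1e-18)

    def test_full_fit_r2_exceeds_090(self, fitted_model):
        assert fitted_model.r_squared_ >= 0.9

    def test_standardization_convention_does_not_move_predictions(self, table1):
        X, y = table1.predictors(), table1.response()
        pop = QuadraticSurfaceRegressor("population").fit(X, y)
        sam = QuadraticSurfaceRegressor("sample").fit(X, y)
        np.testing.assert_allclose(pop.predict(X), sam.predict(X), atol=1e-10)

    def test_f_statistic_invariant_to_affine_rescaling(self, table1):
        X, y = table1.predictors(), table1.response()
        base = QuadraticSurfaceRegressor().fit(X, y)
        rescaled = X * np.array([1 / 7.0, 10.0]) + np.array([3.0, -5.0])
        other = QuadraticSurfaceRegressor().fit(rescaled, y)
        assert other.f_statistic_ == pytest.approx(base.f_statistic_, rel=1e-9)

    def test_rank_deficient_design_raises(self):
        days = np.arange(20, dtype=float)
        X = np.column_stack([days, days])  # x2 == x1: collinear quadratic
        with pytest.raises(SingularDesignError):
            QuadraticSurfaceRegressor().fit(X, np.ones(20))

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            QuadraticSurfaceRegressor().fit(np.ones((5, 2)), np.ones(5))


class TestInference:
    def test_t_equals_estimate_over_se(self, fitted_model):
        inf = fitted_model.inference()
        np.testing.assert_allclose(
            inf.t_value, inf.estimate / inf.se, rtol=1e-9
        )

    def test_ci_brackets_estimate(self, fitted_model):
        inf = fitted_model.inference()
        assert (inf.ci_low <= inf.estimate).all()
        assert (inf.estimate <= inf.ci_high).all()

    def test_term_order(self, fitted_model):
        assert tuple(fitted_model.inference().term) == TERM_NAMES

    def test_type_i_error_rate_near_nominal(self):
        """With a true zero coefficient, the t-test rejects ~5% of the time.

        2000 replicates of intercept-plus-noise data on the study design;
        rejection rate of the linear-time test should sit inside a 3-sigma
        binomial band around 0.05.
        """
        rng = np.random.default_rng(202)
        grid_t = np.repeat(np.linspace(0, 364, 19), 7)
        grid_c = np.tile(np.linspace(1, 88, 7), 19)
        X = np.column_stack([grid_t, grid_c])
        sc = PredictorStandardizer().fit(X)
        D = _design(sc.transform(X))
        n, p = D.shape
        pinv = np.linalg.inv(D.T @ D) @ D.T
        # OLS is linear in y: vectorize over replicates.
        Y = 0.8 + rng.normal(0, 0.02, size=(2000, n))
        B = Y @ pinv.T
        resid = Y - B @ D.T
        s2 = (resid**2).sum(axis=1) / (n - p)
        se1 = np.sqrt(s2 * np.linalg.inv(D.T @ D)[1, 1])
        pvals = 2 * stats.t.sf(np.abs(B[:, 1] / se1), n - p)
        rate = (pvals < 0.05).mean()
        band = 3 * np.sqrt(0.05 * 0.95 / 2000)
        assert abs(rate - 0.05) < band

    def test_parameter_recovery_within_3_se(self):
        """Gaussian noise sigma=0.02, n=133: truth inside 3 SE >=95% of runs."""
        truth = np.array([0.78, -0.17, -0.05, 0.004, -0.02, 0.02])
        grid_t = np.repeat(np.linspace(0, 364, 19), 7)
        grid_c = np.tile(np.linspace(1, 88, 7), 19)
        X = np.column_stack([grid_t, grid_c])
        sc = PredictorStandardizer().fit(X)
        signal = _design(sc.transform(X)) @ truth
        rng = np.random.default_rng(77)
        hits = 0
        for _ in range(500):
            model = QuadraticSurfaceRegressor().fit(
                X, signal + rng.normal(0, 0.02, signal.shape)
            )
            se = np.sqrt(np.diag(model.coef_covariance_))
            if np.all(np.abs(model.coef_ - truth) <= 3 * se):
                hits += 1
        assert hits / 500 >= 0.95


class TestPredict:
    def test_centroid_prediction_is_intercept(self, fitted_model):
        centroid = fitted_model.standardizer_.mean_
        assert fitted_model.predict(centroid) == pytest.approx(
            fitted_model.coef_[0], rel=1e-12
        )

    def test_day0_prediction_near_unity(self, fitted_model):
        assert fitted_model.predict(np.array([0.0, 0.46])) == pytest.approx(1.0, abs=0.10)

    def test_interval_brackets_point(self, fitted_model, rng=np.random.default_rng(5)):
        X = np.column_stack([rng.uniform(0, 364, 25), rng.uniform(0.3, 87, 25)])
        point, lo, hi = fitted_model.predict_interval(X)
        assert np.all(lo <= point) and np.all(point <= hi)
        _, plo, phi = fitted_model.predict_interval(X, kind="prediction")
        assert np.all(plo <= lo) and np.all(hi <= phi)

    def test_unfitted_raises(self):
        from sklearn.exceptions import NotFittedError

        with pytest.raises(NotFittedError):
            QuadraticSurfaceRegressor().predict(np.array([0.0, 1.0]))


class TestSerialization:
    def test_round_trip_is_bit_exact(self, fitted_model, tmp_path):
        path = tmp_path / "model.json"
        fitted_model.to_json(path)
        back = QuadraticSurfaceRegressor.from_json(path)
        assert np.array_equal(back.coef_, fitted_model.coef_)
        assert np.array_equal(back.coef_covariance_, fitted_model.coef_covariance_)
        assert back.residual_variance_ == fitted_model.residual_variance_
        assert np.array_equal(
            back.standardizer_.mean_, fitted_model.standardizer_.mean_
        )
        x = np.array([100.0, 30.0])
        assert back.predict(x) == fitted_model.predict(x)
        # and the re-serialization is byte-identical
        assert back.to_json() == fitted_model.to_json()

    def test_json_is_valid_and_labelled(self, fitted_model):
        d = json.loads(fitted_model.to_json())
        assert d["term_names"] == list(TERM_NAMES)
        assert len(d["coefficients"]) == 6


def test_fit_ols_seeded_determinism(table1):
    a = fit_ols(table1)
    b = fit_ols(table1)
    assert np.array_equal(a.coef_, b.coef_)
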