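"""Standardized second-order polynomial degradation surface (OLS).

The fraction of drug remaining, Y, is modelled as a full quadratic in
two z-scored predictors: storage time at -20 degC (x1, days) and the
measured concentration (x2, mg/L),

    Y = b0 + b1*x1 + b2*x2 + b11*x1^2 + b12*x1*x2 + b22*x2^2.

Coefficients are stored in graded-lexicographic term order
``[1, x1, x2, x1^2, x1*x2, x2^2]`` -- the order in which the published
coefficient values read off term by term.  The overall F-statistic
tests the five non-intercept terms jointly against an intercept-only
model, on (5, n-6) degrees of freedom.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .dataset import PredictorStandardizer, StabilityDataset

TERM_NAMES = ("intercept", "time", "conc", "time_sq", "time_conc", "conc_sq")
N_TERMS = 6


class SingularDesignError(np.linalg.LinAlgError):
    """The quadratic design matrix is rank deficient."""


def build_design_row(x1: float, x2: float) -> np.ndarray:
    """Design row [1, x1, x2, x1^2, x1*x2, x2^2] for standardized inputs."""
    if not (np.isfinite(x1) and np.isfinite(x2)):
        raise ValueError(f"non-finite design input: ({x1}, {x2})")
    return np.array([1.0, x1, x2, x1 * x1, x1 * x2, x2 * x2])


def _design(Z: np.ndarray) -> np.ndarray:
    """Vectorized design matrix from (n, 2) standardized predictors."""
    x1, x2 = Z[:, 0], Z[:, 1]
    return np.column_stack([np.ones_like(x1), x1, x2, x1 * x1, x1 * x2, x2 * x2])


class QuadraticSurfaceRegressor(RegressorMixin, BaseEstimator):
    """OLS quadratic response surface with full coefficient inference.

    Parameters
    ----------
    denominator_convention : {"population", "sample"}
        SD convention for the embedded predictor standardizer.

    Attributes
    ----------
    coef_ : ndarray of shape (6,)
        Coefficients in the order given by :data:`TERM_NAMES`.
    coef_covariance_ : ndarray of shape (6, 6)
        OLS covariance of the coefficients (sigma^2 (X'X)^-1).
    residual_variance_ : float
        RSS / (n - 6).
    df_residual_ : int
    f_statistic_, f_pvalue_ : float
        Overall regression F on (5, n-6) df and its p-value.
    r_squared_ : float
        In-sample coefficient of determination.
    standardizer_ : PredictorStandardizer
        Fitted on the training predictors; applied inside ``predict``.
    time_range_, conc_range_ : tuple of float
        Training ranges of the raw predictors, used by downstream
        back-calculation to flag extrapolation.
    """

    def __init__(
        self,
        denominator_convention: str = "population",
        scale_reference: tuple | None = None,
    ):
        self.denominator_convention = denominator_convention
        # Optional fixed standardization ((mean_t, mean_c), (sd_t, sd_c)):
        # coefficients are then expressed on that scale instead of the
        # training data's own moments.  Predictions are unaffected either
        # way; this matters only when comparing coefficient vectors.
        self.scale_reference = scale_reference

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError(f"X must be (n, 2) [days, measured conc]; got {X.shape}")
        if not (np.isfinite(X).all() and np.isfinite(y).all()):
            raise ValueError("non-finite values in fit data")
        if X.shape[0] < 7:
            raise ValueError("need at least 7 observations to fit 6 coefficients")
        if self.scale_reference is not None:
            sc = PredictorStandardizer(self.denominator_convention)
            sc.mean_ = np.asarray(self.scale_reference[0], dtype=float)
            sc.scale_ = np.asarray(self.scale_reference[1], dtype=float)
            sc.n_features_in_ = 2
            self.standardizer_ = sc
        else:
            self.standardizer_ = PredictorStandardizer(
                self.denominator_convention
            ).fit(X)
        D = _design(self.standardizer_.transform(X))
        if np.linalg.matrix_rank(D) < N_TERMS:
            raise SingularDesignError("rank-deficient quadratic design matrix")
        res = sm.OLS(y, D).fit()
        self.coef_ = np.asarray(res.params)
        self.coef_covariance_ = np.asarray(res.cov_params())
        self.df_residual_ = int(res.df_resid)
        self.residual_variance_ = float(res.mse_resid)
        self.f_statistic_ = float(res.fvalue)
        self.f_pvalue_ = float(res.f_pvalue)
        self.r_squared_ = float(res.rsquared)
        self.n_obs_ = int(res.nobs)
        self.time_range_ = (float(X[:, 0].min()), float(X[:, 0].max()))
        self.conc_range_ = (float(X[:, 1].min()), float(X[:, 1].max()))
        return self

    def _design_raw(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[None, :]
        if not np.isfinite(X).all():
            raise ValueError("non-finite prediction inputs")
        return _design(self.standardizer_.transform(X))

    def predict(self, X) -> np.ndarray:
        """Mean fraction remaining at raw inputs [days, measured conc].

        A single (2,) input returns a scalar; (n, 2) returns (n,).
        """
        check_is_fitted(self, "coef_")
        out = self._design_raw(X) @ self.coef_
        return float(out[0]) if np.asarray(X).ndim == 1 else out

    def predict_interval(self, X, alpha: float = 0.05, kind: str = "confidence"):
        """Point prediction with a symmetric t interval.

        ``kind="confidence"`` gives the mean-response interval
        x'b +/- t * sqrt(x' Sigma x); ``kind="prediction"`` widens it by
        the residual variance for a single new observation.
        """
        check_is_fitted(self, "coef_")
        if not 0 < alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {alpha}")
        D = self._design_raw(X)
        point = D @ self.coef_
        var = np.einsum("ij,jk,ik->i", D, self.coef_covariance_, D)
        if kind == "prediction":
            var = var + self.residual_variance_
        elif kind != "confidence":
            raise ValueError(f"unknown interval kind {kind!r}")
        half = stats.t.ppf(1 - alpha / 2, self.df_residual_) * np.sqrt(var)
        return point, point - half, point + half

    def inference(self, alpha: float = 0.05) -> pd.DataFrame:
        """Per-coefficient estimate, SE, t, two-sided p, and CI.

        SEs come from the coefficient covariance diagonal; the t
        reference distribution has ``df_residual_`` degrees of freedom.
        With zero residual variance the SEs degenerate to 0 and p-values
        to 0 for non-zero estimates.
        """
        check_is_fitted(self, "coef_")
        se = np.sqrt(np.diag(self.coef_covariance_))
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = np.where(se > 0, self.coef_ / np.where(se > 0, se, 1.0), np.inf * np.sign(self.coef_))
        pval = 2 * stats.t.sf(np.abs(tval), self.df_residual_)
        half = stats.t.ppf(1 - alpha / 2, self.df_residual_) * se
        return pd.DataFrame(
            {
                "term": TERM_NAMES,
                "estimate": self.coef_,
                "se": se,
                "t_value": tval,
                "p_value": pval,
                "ci_low": self.coef_ - half,
                "ci_high": self.coef_ + half,
            }
        )

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "model": "quadratic_surface",
            "term_names": list(TERM_NAMES),
            "coefficients": self.coef_.tolist(),
            "coef_covariance": self.coef_covariance_.tolist(),
            "residual_variance": self.residual_variance_,
            "df_residual": self.df_residual_,
            "f_statistic": self.f_statistic_,
            "f_pvalue": self.f_pvalue_,
            "r_squared": self.r_squared_,
            "n_obs": self.n_obs_,
            "denominator_convention": self.denominator_convention,
            "standardizer_mean": self.standardizer_.mean_.tolist(),
            "standardizer_scale": self.standardizer_.scale_.tolist(),
            "time_range": list(self.time_range_),
            "conc_range": list(self.conc_range_),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "QuadraticSurfaceRegressor":
        self = cls(denominator_convention=d["denominator_convention"])
        self.coef_ = np.asarray(d["coefficients"], dtype=float)
        self.coef_covariance_ = np.asarray(d["coef_covariance"], dtype=float)
        self.residual_variance_ = float(d["residual_variance"])
        self.df_residual_ = int(d["df_residual"])
        self.f_statistic_ = float(d["f_statistic"])
        self.f_pvalue_ = float(d["f_pvalue"])
        self.r_squared_ = float(d["r_squared"])
        self.n_obs_ = int(d["n_obs"])
        sc = PredictorStandardizer(d["denominator_convention"])
        sc.mean_ = np.asarray(d["standardizer_mean"], dtype=float)
        sc.scale_ = np.asarray(d["standardizer_scale"], dtype=float)
        sc.n_features_in_ = 2
        self.standardizer_ = sc
        self.time_range_ = tuple(d["time_range"])
        self.conc_range_ = tuple(d["conc_range"])
        return self

    @classmethod
    def from_json(cls, source: str | Path) -> "QuadraticSurfaceRegressor":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        return cls.from_dict(json.loads(text))


def fit_ols(
    dataset: StabilityDataset,
    response: str = "baseline",
    denominator_convention: str = "population",
) -> QuadraticSurfaceRegressor:
    """Fit the quadratic surface to a stability dataset."""
    model = QuadraticSurfaceRegressor(denominator_convention=denominator_convention)
    return model.fit(dataset.predictors(), dataset.response(response))


def file_sha256(path: str | Path) -> str:
    """Hex digest of a file, for run provenance logs."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
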