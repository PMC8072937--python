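"""Feed-forward tanh network for the degradation surface.

A deliberately small multilayer perceptron: two input neurons (z-scored
storage time and measured concentration), one or two tanh hidden layers
of 2-32 neurons, one linear output neuron (fraction remaining).  Weights
minimize MSE plus an L2 penalty (1e-4 to 1e-1) and are optimized with
L-BFGS; training is deterministic given a seed.

Hyperparameters (layout and penalty) are chosen by an inner
leave-one-experiment-out loop: the candidate with the lowest mean
validation MSE wins, with ties broken toward fewer parameters and then
a larger penalty.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPRegressor
from sklearn.utils.validation import check_is_fitted

from .dataset import PredictorStandardizer

NEURON_RANGE = (2, 32)
PENALTY_RANGE = (1e-4, 1e-1)


def tanh_activation(x):
    """Hyperbolic tangent (e^x - e^-x)/(e^x + e^-x); odd, range (-1, 1)."""
    return np.tanh(x)


def _validate_layout(hidden_layout: Sequence[int]) -> tuple[int, ...]:
    layout = tuple(int(n) for n in hidden_layout)
    if not 1 <= len(layout) <= 2:
        raise ValueError(f"hidden_layout must have 1 or 2 layers, got {layout}")
    for n in layout:
        if not NEURON_RANGE[0] <= n <= NEURON_RANGE[1]:
            raise ValueError(
                f"neurons per layer must be in {NEURON_RANGE}, got {layout}"
            )
    return layout


@dataclass(frozen=True)
class AnnHyperparams:
    """One grid point: hidden layout, L2 penalty, seed, iteration cap."""

    hidden_layout: tuple[int, ...] = (8,)
    l2_penalty: float = 1e-4
    seed: int = 0
    max_iterations: int = 5000

    def __post_init__(self):
        object.__setattr__(self, "hidden_layout", _validate_layout(self.hidden_layout))
        if not PENALTY_RANGE[0] <= self.l2_penalty <= PENALTY_RANGE[1]:
            raise ValueError(
                f"l2_penalty must be in {PENALTY_RANGE}, got {self.l2_penalty}"
            )

    @property
    def n_parameters(self) -> int:
        """Weight + bias count for a 2-input, 1-output network."""
        widths = (2, *self.hidden_layout, 1)
        return sum(a * b + b for a, b in zip(widths[:-1], widths[1:]))


def default_grid(seed: int = 0, max_iterations: int = 5000) -> list[AnnHyperparams]:
    """40 candidates: widths {2,4,8,16,32} x {1,2} layers x 4 penalties.

    Log-spaced coverage of the admissible ranges; two-layer candidates
    repeat the same width in both layers.
    """
    grid = []
    for n_layers in (1, 2):
        for width in (2, 4, 8, 16, 32):
            for penalty in (1e-4, 1e-3, 1e-2, 1e-1):
                grid.append(
                    AnnHyperparams((width,) * n_layers, penalty, seed, max_iterations)
                )
    return grid


class TanhMLPRegressor(RegressorMixin, BaseEstimator):
    """Small tanh MLP with internal predictor standardization.

    Wraps the scikit-learn multilayer perceptron (tanh activation,
    L-BFGS solver, ``alpha`` = L2 penalty) behind the package's
    estimator surface, with the predictor standardizer fitted on the
    training data only.

    Attributes
    ----------
    mlp_ : fitted sklearn MLPRegressor
    standardizer_ : PredictorStandardizer
    converged_ : bool
    final_mse_ : float
        Training MSE of the fitted network (penalty excluded).
    """

    def __init__(
        self,
        hidden_layout: Sequence[int] = (8,),
        l2_penalty: float = 1e-4,
        random_state: int = 0,
        max_iter: int = 5000,
        tol: float = 1e-8,
    ):
        self.hidden_layout = hidden_layout
        self.l2_penalty = l2_penalty
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        layout = _validate_layout(self.hidden_layout)
        if not PENALTY_RANGE[0] <= self.l2_penalty <= PENALTY_RANGE[1]:
            raise ValueError(
                f"l2_penalty must be in {PENALTY_RANGE}, got {self.l2_penalty}"
            )
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError(f"X must be (n, 2); got {X.shape}")
        self.standardizer_ = PredictorStandardizer().fit(X)
        Z = self.standardizer_.transform(X)
        self.mlp_ = MLPRegressor(
            hidden_layer_sizes=layout,
            activation="tanh",
            solver="lbfgs",
            alpha=self.l2_penalty,
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=self.random_state,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.mlp_.fit(Z, y)
        self.converged_ = self.mlp_.n_iter_ < self.max_iter
        if not self.converged_:
            warnings.warn(
                f"L-BFGS stopped at the {self.max_iter}-iteration cap", RuntimeWarning
            )
        resid = self.mlp_.predict(Z) - y
        self.final_mse_ = float(np.mean(resid**2))
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "mlp_")
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[None, :]
        out = self.mlp_.predict(self.standardizer_.transform(X))
        return out[0] if squeeze else out

    def to_dict(self) -> dict:
        check_is_fitted(self, "mlp_")
        return {
            "model": "tanh_mlp",
            "hidden_layout": list(_validate_layout(self.hidden_layout)),
            "l2_penalty": self.l2_penalty,
            "random_state": self.random_state,
            "max_iter": self.max_iter,
            "tol": self.tol,
            "converged": bool(self.converged_),
            "final_mse": self.final_mse_,
            "standardizer_mean": self.standardizer_.mean_.tolist(),
            "standardizer_scale": self.standardizer_.scale_.tolist(),
            "layer_shapes": [list(w.shape) for w in self.mlp_.coefs_],
            "weights": [w.ravel().tolist() for w in self.mlp_.coefs_],
            "biases": [b.tolist() for b in self.mlp_.intercepts_],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict())
        if path is not None:
            Path(path).write_text(text)
        return text


def select_hyperparams(
    X,
    y,
    groups,
    grid: Sequence[AnnHyperparams],
    random_state: int = 0,
) -> AnnHyperparams:
    """Pick the grid point with the lowest mean validation MSE.

    The folds are leave-one-experiment-out over ``groups`` (one fold
    per unique group).  Ties are broken by (fewer parameters, larger
    penalty, grid order).  Raises if every candidate fails to fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("need >=2 experiments for inner validation folds")
    if len(grid) == 0:
        raise ValueError("empty hyperparameter grid")
    scored = []
    for order, hp in enumerate(grid):
        fold_mse = []
        for level in levels:
            test = groups == level
            try:
                model = TanhMLPRegressor(
                    hp.hidden_layout,
                    hp.l2_penalty,
                    random_state=random_state if hp.seed is None else hp.seed,
                    max_iter=hp.max_iterations,
                ).fit(X[~test], y[~test])
            except Exception:
                fold_mse = None
                break
            resid = model.predict(X[test]) - y[test]
            fold_mse.append(float(np.mean(resid**2)))
        if fold_mse is not None:
            scored.append((np.mean(fold_mse), hp.n_parameters, -hp.l2_penalty, order, hp))
    if not scored:
        raise RuntimeError("hyperparameter selection failed: no candidate fitted")
    return min(scored)[-1]
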