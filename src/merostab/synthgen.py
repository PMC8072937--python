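"""Synthetic stability datasets with a known ground-truth surface.

The generator mirrors the study design: a grid of spiked levels times
storage days, a smooth quadratic degradation surface on a fixed
standardized scale, and multiplicative Gaussian measurement noise
(analytical CV).  Because the true surface's predictor is the measured
concentration, noise-free measurements come from the same fixed-point
construction used in forward simulation, so fitted and true
coefficients are directly comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import StabilityDataset, load_table1
from .polymodel import QuadraticSurfaceRegressor, TERM_NAMES
from .simulate import solve_measured

# Default truth: the study-fitted surface, printed precision.
# Order: intercept, time, conc, time^2, time*conc, conc^2.
DEFAULT_COEFFICIENTS = (0.779, -0.166, -0.046, 0.004, -0.021, 0.019)

DEFAULT_SPIKED_LEVELS = (0.44, 4.38, 17.5, 35.1, 52.6, 70.1, 87.6)
DEFAULT_DAY_GRID = (
    0, 7, 14, 21, 28, 42, 56, 70, 84, 112, 140, 168, 196, 224, 252, 280, 308, 336, 364
)


def _reference_moments() -> tuple[tuple[float, float], tuple[float, float]]:
    """Standardizer moments of the packaged study table (population SD)."""
    ds = load_table1()
    X = ds.predictors()
    return (
        (float(X[:, 0].mean()), float(X[:, 0].std())),
        (float(X[:, 1].mean()), float(X[:, 1].std())),
    )


@dataclass
class SynthConfig:
    """Design and noise settings for one synthetic dataset.

    ``standardizer_reference`` fixes the standardized scale the true
    coefficients live on, as ((time mean, time sd), (conc mean, conc sd));
    by default the packaged study table's moments, so the default truth
    is the study's own fitted surface.  ``noise_cv`` is the analytical
    coefficient of variation of the multiplicative measurement error
    (0.05 default, well inside the 15% acceptability band of
    bioanalytical method validation).
    """

    true_coefficients: tuple[float, ...] = DEFAULT_COEFFICIENTS
    spiked_levels: tuple[float, ...] = DEFAULT_SPIKED_LEVELS
    day_grid: tuple[int, ...] = DEFAULT_DAY_GRID
    noise_cv: float = 0.05
    seed: int = 0
    standardizer_reference: tuple | None = None

    def __post_init__(self):
        if len(self.true_coefficients) != 6:
            raise ValueError("true_coefficients must have 6 entries")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if any(d < 0 for d in self.day_grid):
            raise ValueError("day_grid must be non-negative")
        if any(c <= 0 for c in self.spiked_levels):
            raise ValueError("spiked_levels must be positive")

    def resolved_reference(self):
        return (
            self.standardizer_reference
            if self.standardizer_reference is not None
            else _reference_moments()
        )

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "true_coefficients": list(self.true_coefficients),
            "term_names": list(TERM_NAMES),
            "spiked_levels": list(self.spiked_levels),
            "day_grid": list(self.day_grid),
            "noise_cv": self.noise_cv,
            "seed": self.seed,
            "standardizer_reference": [list(m) for m in self.resolved_reference()],
        }
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def true_model(config: SynthConfig) -> QuadraticSurfaceRegressor:
    """The generating surface as a ready-to-predict fitted model."""
    (mt, st), (mc, sc) = config.resolved_reference()
    model = QuadraticSurfaceRegressor.from_dict(
        {
            "denominator_convention": "population",
            "coefficients": list(config.true_coefficients),
            "coef_covariance": np.zeros((6, 6)).tolist(),
            "residual_variance": 0.0,
            "df_residual": 1,
            "f_statistic": 0.0,
            "f_pvalue": 1.0,
            "r_squared": 1.0,
            "n_obs": 0,
            "standardizer_mean": [mt, mc],
            "standardizer_scale": [st, sc],
            "time_range": [min(config.day_grid), max(config.day_grid)],
            "conc_range": [0.0, max(config.spiked_levels) * 1.2],
        }
    )
    return model


def generate(config: SynthConfig) -> tuple[StabilityDataset, np.ndarray]:
    """Draw one dataset; returns it with the noise-free measured concs.

    For each (spiked level, day) the noise-free measurement is the
    fixed point of the true surface; the observation multiplies it by
    (1 + eps), eps ~ N(0, noise_cv), truncated at zero.
    """
    model = true_model(config)
    rng = np.random.default_rng(config.seed)
    c0s = np.repeat(config.spiked_levels, len(config.day_grid)).astype(float)
    days = np.tile(config.day_grid, len(config.spiked_levels)).astype(float)
    # All fixed points iterated in lock-step; the map is a contraction
    # everywhere the surface is sensible, and any stragglers fall back
    # to the scalar solver with its bracketing safety net.
    cts = c0s.copy()
    for _ in range(200):
        nxt = c0s * model.predict(np.column_stack([days, cts]))
        if np.all(np.abs(nxt - cts) <= 1e-12 * c0s):
            cts = nxt
            break
        cts = nxt
    else:
        cts = np.array(
            [solve_measured(model, c, d) for c, d in zip(c0s, days)]
        )
    if np.any(cts <= 0):
        i = int(np.argmin(cts))
        raise ValueError(
            f"true surface gives non-positive concentration at "
            f"({c0s[i]} mg/L, day {days[i]:.0f})"
        )
    obs = np.maximum(cts * (1.0 + rng.normal(0.0, config.noise_cv, cts.shape)), 0.0)
    frame = pd.DataFrame(
        {
            "spiked_mg_per_L": c0s,
            "day": days.astype(int),
            "measured_mg_per_L": obs,
        }
    )
    return StabilityDataset(frame), cts


def recover_coefficients(
    dataset: StabilityDataset,
    config: SynthConfig,
    response: str = "spiked",
    true_concentrations: np.ndarray | None = None,
) -> np.ndarray:
    """Refit the quadratic surface on the config's standardized scale.

    Expressing the fit on the same fixed scale the truth lives on makes
    the recovered vector directly comparable to
    ``config.true_coefficients`` (predictions do not depend on the
    scale; the coefficient parameterization does).

    With measurement noise the observed concentration is a noisy
    *predictor* as well as part of the response, so a plain refit is
    attenuated (errors-in-variables).  Passing the generator's
    ``true_concentrations`` substitutes the noise-free predictor and
    isolates the estimator's own bias.
    """
    (mt, st), (mc, sc) = config.resolved_reference()
    model = QuadraticSurfaceRegressor(scale_reference=((mt, mc), (st, sc)))
    X = dataset.predictors()
    if true_concentrations is not None:
        X = np.column_stack([X[:, 0], np.asarray(true_concentrations, dtype=float)])
    model.fit(X, dataset.response(response))
    return model.coef_


def make_fixture_like(config: SynthConfig | None = None) -> StabilityDataset:
    """Convenience: a dataset shaped exactly like the study table."""
    return generate(config if config is not None else SynthConfig())[0]
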