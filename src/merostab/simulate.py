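"""Forward simulation of degradation and back-calculation.

The fitted surface predicts the fraction remaining Y from (storage day,
*measured* concentration).  To simulate forward from an initial
concentration C0 the measured concentration at day t is the unknown, so
each day solves the fixed-point equation

    Ct = C0 * f(t, Ct)

by iteration from Ct = C0 (bracketed root-finding as fallback).
Degradation is declared significant on the first day the lower bound of
the mean-response confidence interval drops below the stability
threshold (85% by default; 80% is the usual variant near the lower
limit of quantification).  Uncertainty in the solved Ct itself is not
propagated into the interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .polymodel import QuadraticSurfaceRegressor


class SimulationError(RuntimeError):
    """The fixed-point equation has no solution in the search bracket."""


class BackCalculationError(ValueError):
    """The model predicts a non-positive remaining fraction."""


def solve_measured(
    model: QuadraticSurfaceRegressor,
    spiked: float,
    day: float,
    rtol: float = 1e-9,
    max_iter: int = 100,
) -> float:
    """Measured concentration Ct* consistent with initial conc ``spiked``.

    Solves Ct = spiked * f(day, Ct) by fixed-point iteration from
    Ct = spiked; if the iteration does not contract, falls back to
    bracketed root finding on [0, 1.2 * spiked].
    """
    if not spiked > 0:
        raise ValueError(f"spiked must be > 0, got {spiked}")
    ct = float(spiked)
    for _ in range(max_iter):
        nxt = spiked * float(model.predict(np.array([day, ct])))
        if abs(nxt - ct) <= rtol * spiked:
            return nxt
        ct = nxt

    def gap(c):
        return c - spiked * float(model.predict(np.array([day, c])))

    lo, hi = 0.0, 1.2 * spiked
    if gap(lo) * gap(hi) > 0:
        raise SimulationError(
            f"no fixed point in [0, {hi:g}] at day {day} for spiked {spiked:g}"
        )
    return float(brentq(gap, lo, hi, xtol=rtol * spiked))


@dataclass
class Trajectory:
    """Simulated remaining-fraction curve with its confidence band."""

    spiked_conc: float
    days: np.ndarray
    remaining: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    threshold: float
    significant_day: int | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.days,
                "remaining_pct": self.remaining * 100,
                "ci_low_pct": self.ci_low * 100,
                "ci_high_pct": self.ci_high * 100,
            }
        )

    def summary(self) -> dict:
        return {
            "spiked_mg_per_L": self.spiked_conc,
            "threshold": self.threshold,
            "significant_day": self.significant_day,
        }


def simulate_trajectory(
    model: QuadraticSurfaceRegressor,
    spiked: float,
    horizon: int = 364,
    threshold: float = 0.85,
    alpha: float = 0.05,
    interval: str = "confidence",
) -> Trajectory:
    """Daily trajectory from day 0 to ``horizon`` for one initial conc.

    Each day solves the fixed-point measured concentration, then
    evaluates the model's mean-response interval there.  The first grid
    day whose lower bound falls below ``threshold`` is reported as the
    significant-degradation day (integer-day grid, no interpolation).
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    days = np.arange(horizon + 1)
    cts = np.empty(days.shape)
    for i, day in enumerate(days):
        try:
            cts[i] = solve_measured(model, spiked, day)
        except SimulationError as exc:
            raise SimulationError(f"day {day}: {exc}") from exc
    point, lo, hi = model.predict_interval(
        np.column_stack([days, cts]), alpha=alpha, kind=interval
    )
    below = np.nonzero(lo < threshold)[0]
    sig = int(days[below[0]]) if len(below) else None
    return Trajectory(float(spiked), days, point, lo, hi, threshold, sig)


@dataclass
class BackCalcResult:
    """Pre-storage concentration estimated from a degraded measurement."""

    measured_conc: float
    storage_days: float
    predicted_remaining: float
    estimated_initial: float
    extrapolation_flag: bool

    def to_dict(self) -> dict:
        return {
            "measured_mg_per_L": self.measured_conc,
            "storage_days": self.storage_days,
            "predicted_remaining": self.predicted_remaining,
            "estimated_initial_mg_per_L": self.estimated_initial,
            "extrapolation": self.extrapolation_flag,
        }


def back_calculate(
    model: QuadraticSurfaceRegressor, measured: float, storage_days: float
) -> BackCalcResult:
    """Estimate the initial concentration: measured / predicted remaining.

    ``extrapolation_flag`` is set when the inputs fall outside the
    ranges the model was fitted on.
    """
    if not measured > 0:
        raise ValueError(f"measured must be > 0, got {measured}")
    if storage_days < 0:
        raise ValueError(f"storage_days must be >= 0, got {storage_days}")
    remaining = float(model.predict(np.array([storage_days, measured])))
    if remaining <= 0:
        raise BackCalculationError(
            f"model predicts non-positive remaining fraction ({remaining:.4f}) "
            f"at day {storage_days}, {measured} mg/L"
        )
    t_lo, t_hi = getattr(model, "time_range_", (0.0, 364.0))
    c_lo, c_hi = getattr(model, "conc_range_", (0.30, 86.9))
    outside = not (t_lo <= storage_days <= t_hi and c_lo <= measured <= c_hi)
    return BackCalcResult(
        measured_conc=float(measured),
        storage_days=float(storage_days),
        predicted_remaining=remaining,
        estimated_initial=float(measured) / remaining,
        extrapolation_flag=outside,
    )
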