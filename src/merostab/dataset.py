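"""Stability-experiment tables: loading, validation, and standardization.

A stability experiment spikes drug-free plasma at a known concentration
(C0, mg/L), stores aliquots at -20 degC for a grid of durations, and
measures the remaining concentration (Ct, mg/L).  The packaged study
table holds 7 spiked levels x 19 storage days = 133 mean measurements.

Two reference scales for the "fraction remaining" response are supported:

``baseline``
    Ct divided by the experiment's *measured* day-0 concentration (the
    sample kept at -80 degC throughout).  This is the scale on which the
    published degradation surface lives: the day-0 measurement absorbs
    the analytical offset between nominal and recovered concentration.
``spiked``
    Ct divided by the nominal spiked concentration.  Day-0 values then
    sit at 94-105% rather than exactly 100%.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

REQUIRED_COLUMNS = ("spiked_mg_per_L", "day", "measured_mg_per_L")

_FIXTURE_NAME = "table1_meropenem.csv"


class SchemaError(ValueError):
    """The input table does not have the expected structure."""


class ValidationError(ValueError):
    """A row violates a record invariant."""


def relative_remaining(measured: float, spiked: float) -> float:
    """Fraction of drug remaining: measured concentration over spiked.

    No clamping is applied; day-0 measurements may exceed the nominal
    spiked concentration, so values slightly above 1 are legitimate.
    """
    spiked = float(spiked)
    if not spiked > 0:
        raise ValueError(f"spiked concentration must be positive, got {spiked}")
    return float(measured) / spiked


@dataclass(frozen=True)
class StabilityRecord:
    """One mean measurement: (spiked conc, storage days, measured conc)."""

    spiked_conc: float
    storage_days: int
    measured_conc: float

    def __post_init__(self) -> None:
        if not self.spiked_conc > 0:
            raise ValidationError(f"spiked_conc must be > 0, got {self.spiked_conc}")
        if self.measured_conc < 0:
            raise ValidationError(f"measured_conc must be >= 0, got {self.measured_conc}")
        if self.storage_days < 0:
            raise ValidationError(f"storage_days must be >= 0, got {self.storage_days}")

    @property
    def relative_remaining(self) -> float:
        return relative_remaining(self.measured_conc, self.spiked_conc)


class StabilityDataset:
    """An ordered collection of stability records for >=1 experiments.

    One "experiment" is the full time series of a single spiked
    concentration; experiments are labelled E1, E2, ... in order of
    increasing spiked concentration.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.reset_index(drop=True)
        for col in REQUIRED_COLUMNS:
            if col not in frame.columns:
                raise SchemaError(f"missing required column {col!r}")
        if len(frame) == 0:
            raise SchemaError("empty table: no records")
        for col in REQUIRED_COLUMNS:
            bad = frame.index[~np.isfinite(frame[col].astype(float))]
            if len(bad):
                raise ValidationError(f"non-finite value in {col!r} at row {bad[0]}")
        neg = frame.index[(frame["spiked_mg_per_L"] <= 0)]
        if len(neg):
            raise ValidationError(
                f"spiked concentration must be > 0 (row {neg[0]}: "
                f"{frame.loc[neg[0], 'spiked_mg_per_L']})"
            )
        neg = frame.index[(frame["measured_mg_per_L"] < 0)]
        if len(neg):
            raise ValidationError(
                f"negative measured concentration at row {neg[0]}: "
                f"{frame.loc[neg[0], 'measured_mg_per_L']}"
            )
        neg = frame.index[(frame["day"] < 0)]
        if len(neg):
            raise ValidationError(f"negative storage day at row {neg[0]}")
        dup = frame.duplicated(subset=["spiked_mg_per_L", "day"])
        if dup.any():
            row = frame[dup].iloc[0]
            raise ValidationError(
                "duplicate (spiked, day) pair: "
                f"({row['spiked_mg_per_L']}, {row['day']})"
            )
        self._frame = frame[list(REQUIRED_COLUMNS)].astype(
            {"spiked_mg_per_L": float, "day": int, "measured_mg_per_L": float}
        )

    # -- basic introspection -------------------------------------------------

    def __len__(self) -> int:
        return len(self._frame)

    @property
    def spiked_levels(self) -> np.ndarray:
        """Sorted unique spiked concentrations (mg/L)."""
        return np.sort(self._frame["spiked_mg_per_L"].unique())

    @property
    def experiment_labels(self) -> dict[float, str]:
        """Mapping spiked concentration -> label E1..En (ascending)."""
        return {c: f"E{i + 1}" for i, c in enumerate(self.spiked_levels)}

    @property
    def n_experiments(self) -> int:
        return len(self.spiked_levels)

    @property
    def records(self) -> list[StabilityRecord]:
        return [
            StabilityRecord(r.spiked_mg_per_L, int(r.day), r.measured_mg_per_L)
            for r in self._frame.itertuples()
        ]

    def to_frame(self) -> pd.DataFrame:
        """Copy of the underlying long-format table."""
        return self._frame.copy()

    # -- modelling views -----------------------------------------------------

    def baseline_map(self) -> dict[float, float]:
        """Per-experiment reference concentration: day-0 measurement.

        Falls back to the nominal spiked concentration for experiments
        without a day-0 record.
        """
        out: dict[float, float] = {}
        for c in self.spiked_levels:
            sub = self._frame[self._frame["spiked_mg_per_L"] == c]
            at0 = sub[sub["day"] == 0]
            out[float(c)] = float(at0["measured_mg_per_L"].iloc[0]) if len(at0) else float(c)
        return out

    def predictors(self) -> np.ndarray:
        """(n, 2) array of raw predictors: [storage days, measured conc]."""
        return self._frame[["day", "measured_mg_per_L"]].to_numpy(dtype=float)

    def response(self, kind: str = "baseline") -> np.ndarray:
        """Fraction-remaining response on the requested reference scale."""
        if kind == "spiked":
            ref = self._frame["spiked_mg_per_L"].to_numpy()
        elif kind == "baseline":
            bmap = self.baseline_map()
            ref = self._frame["spiked_mg_per_L"].map(bmap).to_numpy()
        else:
            raise ValueError(f"unknown response kind {kind!r}")
        return self._frame["measured_mg_per_L"].to_numpy() / ref

    def groups(self) -> np.ndarray:
        """Experiment membership for each record (the spiked level)."""
        return self._frame["spiked_mg_per_L"].to_numpy()

    def select(self, spiked: Iterable[float] | float, invert: bool = False) -> "StabilityDataset":
        """Subset by spiked level(s); ``invert=True`` drops them instead."""
        levels = np.atleast_1d(np.asarray(spiked, dtype=float))
        mask = self._frame["spiked_mg_per_L"].isin(levels)
        if invert:
            mask = ~mask
        return StabilityDataset(self._frame[mask])

    def summary(self) -> dict:
        """Counts and per-experiment ranges, JSON-serializable."""
        per = {}
        labels = self.experiment_labels
        for c in self.spiked_levels:
            sub = self._frame[self._frame["spiked_mg_per_L"] == c]
            per[labels[c]] = {
                "spiked_mg_per_L": float(c),
                "n": int(len(sub)),
                "day_range": [int(sub["day"].min()), int(sub["day"].max())],
                "measured_range": [
                    float(sub["measured_mg_per_L"].min()),
                    float(sub["measured_mg_per_L"].max()),
                ],
            }
        return {
            "n_records": len(self),
            "n_experiments": self.n_experiments,
            "experiments": per,
        }


def load_dataset(path: str | Path) -> StabilityDataset:
    """Read a long-format CSV (``spiked_mg_per_L,day,measured_mg_per_L``).

    Comma separated, period decimal, header row, UTF-8.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    try:
        frame = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty file: {path}") from exc
    return StabilityDataset(frame)


def load_table1() -> StabilityDataset:
    """The packaged -20 degC study table (7 experiments x 19 days)."""
    with resources.as_file(
        resources.files("merostab.data").joinpath(_FIXTURE_NAME)
    ) as p:
        return load_dataset(p)


class PredictorStandardizer(TransformerMixin, BaseEstimator):
    """Per-column z-scoring with an explicit SD denominator convention.

    Parameters
    ----------
    denominator_convention : {"population", "sample"}
        ``"population"`` divides by the SD with denominator n (the
        default of the usual machine-learning scalers), ``"sample"`` by
        the n-1 version.  For this package's quadratic surface the
        choice does not move predictions (the model class is closed
        under affine predictor maps), only the printed coefficients.
    """

    def __init__(self, denominator_convention: str = "population"):
        self.denominator_convention = denominator_convention

    def fit(self, X, y=None):
        if self.denominator_convention not in ("population", "sample"):
            raise ValueError(
                f"unknown denominator_convention {self.denominator_convention!r}"
            )
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        ddof = 0 if self.denominator_convention == "population" else 1
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to standardize")
        for j in range(X.shape[1]):
            if len(np.unique(X[:, j])) < 2:
                raise ValueError(f"predictor column {j} is constant; scale undefined")
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=ddof)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[:, None]
        out = (X - self.mean_) / self.scale_
        return out[:, 0] if squeeze else out

    def inverse_transform(self, X):
        X = np.asarray(X, dtype=float)
        squeeze = X.ndim == 1
        if squeeze:
            X = X[:, None]
        out = X * self.scale_ + self.mean_
        return out[:, 0] if squeeze else out
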