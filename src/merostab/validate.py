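"""Leave-one-experiment-out validation and agreement analysis.

One fold per spiked-concentration experiment: the held-out set is that
experiment's full time series, so the score measures generalization to
an unseen concentration.  The polynomial is validated non-nested; the
network adds an inner leave-one-experiment-out loop over the training
experiments for hyperparameter selection, keeping model selection,
fitting, and evaluation on disjoint data.

Metrics are reported on the percentage-remaining scale (Y x 100):
per-experiment RMSE and R^2 (the held-out experiment's own mean as
baseline), plus pooled Pearson correlation and Bland-Altman agreement
between held-out predictions and observations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import LeaveOneGroupOut

from .annmodel import AnnHyperparams, TanhMLPRegressor, default_grid, select_hyperparams
from .dataset import StabilityDataset
from .polymodel import QuadraticSurfaceRegressor
from .simulate import solve_measured


class Fold(NamedTuple):
    label: str
    spiked_conc: float
    train: StabilityDataset
    test: StabilityDataset


def loeo_folds(dataset: StabilityDataset) -> list[Fold]:
    """One (train, test) split per experiment, ordered by spiked conc."""
    levels = dataset.spiked_levels
    if len(levels) < 2:
        raise ValueError("leave-one-experiment-out needs >=2 experiments")
    labels = dataset.experiment_labels
    splitter = LeaveOneGroupOut()
    frame = dataset.to_frame()
    groups = dataset.groups()
    folds = []
    for train_idx, test_idx in splitter.split(frame, groups=groups):
        level = float(groups[test_idx[0]])
        folds.append(
            Fold(
                labels[level],
                level,
                StabilityDataset(frame.iloc[train_idx]),
                StabilityDataset(frame.iloc[test_idx]),
            )
        )
    folds.sort(key=lambda f: f.spiked_conc)
    return folds


def _rmse_r2(obs: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    resid = obs - pred
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    return rmse, 1.0 - float(np.sum(resid**2)) / ss_tot


@dataclass
class CvReport:
    """Per-experiment held-out metrics plus pooled prediction pairs."""

    per_experiment: pd.DataFrame  # label, spiked_conc, rmse_pct, r2
    observed: np.ndarray  # pooled held-out observations, %
    predicted: np.ndarray  # pooled held-out predictions, %
    model_name: str

    @property
    def summary(self) -> dict:
        r = self.per_experiment
        return {
            "model": self.model_name,
            "mean_rmse_pct": float(r["rmse_pct"].mean()),
            "sd_rmse_pct": float(r["rmse_pct"].std(ddof=1)),
            "mean_r2": float(r["r2"].mean()),
            "sd_r2": float(r["r2"].std(ddof=1)),
        }

    def to_frame(self) -> pd.DataFrame:
        """Per-experiment rows plus a mean +/- SD summary row."""
        s = self.summary
        summary_row = pd.DataFrame(
            [
                {
                    "label": "mean±sd",
                    "spiked_conc": np.nan,
                    "rmse_pct": s["mean_rmse_pct"],
                    "r2": s["mean_r2"],
                }
            ]
        )
        return pd.concat([self.per_experiment, summary_row], ignore_index=True)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "summary": self.summary,
            "per_experiment": self.per_experiment.to_dict(orient="records"),
            "observed_pct": self.observed.tolist(),
            "predicted_pct": self.predicted.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def cross_validate_poly(
    dataset: StabilityDataset,
    response: str = "baseline",
    denominator_convention: str = "population",
    predict_mode: str = "direct",
) -> CvReport:
    """Non-nested LOEO validation of the quadratic surface.

    ``predict_mode="direct"`` plugs each held-out record's observed
    (day, measured conc) into the trained surface.  ``"trajectory"``
    instead simulates the held-out experiment forward from its own
    reference concentration via the fixed-point solve, so predictions
    use only the storage day and the initial concentration.
    """
    if predict_mode not in ("direct", "trajectory"):
        raise ValueError(f"unknown predict_mode {predict_mode!r}")
    rows, obs_all, pred_all = [], [], []
    for fold in loeo_folds(dataset):
        model = QuadraticSurfaceRegressor(denominator_convention).fit(
            fold.train.predictors(), fold.train.response(response)
        )
        obs = fold.test.response(response) * 100
        if predict_mode == "direct":
            pred = model.predict(fold.test.predictors()) * 100
        else:
            ref = (
                fold.test.baseline_map()[fold.spiked_conc]
                if response == "baseline"
                else fold.spiked_conc
            )
            days = fold.test.predictors()[:, 0]
            pred = np.array(
                [solve_measured(model, ref, d) / ref for d in days]
            ) * 100
        rmse, r2 = _rmse_r2(obs, pred)
        rows.append(
            {"label": fold.label, "spiked_conc": fold.spiked_conc, "rmse_pct": rmse, "r2": r2}
        )
        obs_all.append(obs)
        pred_all.append(pred)
    return CvReport(
        pd.DataFrame(rows), np.concatenate(obs_all), np.concatenate(pred_all), "poly"
    )


def cross_validate_ann(
    dataset: StabilityDataset,
    grid: Sequence[AnnHyperparams] | None = None,
    seed: int = 0,
    response: str = "baseline",
) -> CvReport:
    """Nested LOEO validation of the tanh network.

    Outer loop: hold out one experiment.  Inner loop: LOEO over the
    remaining experiments scores every grid candidate by mean
    validation MSE; the winner is refit on the full outer-training set
    and evaluated once on the held-out experiment.
    """
    if grid is None:
        grid = default_grid(seed=seed)
    if len(grid) == 0:
        raise ValueError("empty hyperparameter grid")
    rows, obs_all, pred_all, chosen = [], [], [], []
    for fold in loeo_folds(dataset):
        Xtr, ytr = fold.train.predictors(), fold.train.response(response)
        hp = select_hyperparams(Xtr, ytr, fold.train.groups(), grid, random_state=seed)
        model = TanhMLPRegressor(
            hp.hidden_layout, hp.l2_penalty, random_state=hp.seed, max_iter=hp.max_iterations
        ).fit(Xtr, ytr)
        obs = fold.test.response(response) * 100
        pred = model.predict(fold.test.predictors()) * 100
        rmse, r2 = _rmse_r2(obs, pred)
        rows.append(
            {"label": fold.label, "spiked_conc": fold.spiked_conc, "rmse_pct": rmse, "r2": r2}
        )
        obs_all.append(obs)
        pred_all.append(pred)
        chosen.append(hp)
    report = CvReport(
        pd.DataFrame(rows), np.concatenate(obs_all), np.concatenate(pred_all), "ann"
    )
    report.selected_hyperparams = chosen
    return report


@dataclass
class AgreementReport:
    """Pearson correlation and Bland-Altman agreement statistics.

    Differences are prediction minus observation, in percentage points;
    a negative bias therefore means the model under-predicts.
    """

    n: int
    pearson_r: float
    r_ci: tuple[float, float]
    r_pvalue: float
    bias: float
    bias_ci: tuple[float, float]
    bias_pvalue: float
    sd_diff: float
    loa_low: float
    loa_high: float
    loa_low_ci: tuple[float, float]
    loa_high_ci: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "pearson_r": self.pearson_r,
            "pearson_r_ci95": list(self.r_ci),
            "correlation_pvalue": self.r_pvalue,
            "bias_pct": self.bias,
            "bias_ci95": list(self.bias_ci),
            "bias_pvalue": self.bias_pvalue,
            "sd_diff_pct": self.sd_diff,
            "loa_low_pct": self.loa_low,
            "loa_high_pct": self.loa_high,
            "loa_low_ci95": list(self.loa_low_ci),
            "loa_high_ci95": list(self.loa_high_ci),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def agreement_analysis(
    observed: np.ndarray, predicted: np.ndarray, alpha: float = 0.05
) -> AgreementReport:
    """Correlation and Bland-Altman agreement on paired percentages.

    Pearson r comes with a Fisher-z confidence interval and the n-2 df
    correlation t-test.  Limits of agreement are bias +/- 1.96 * SD of
    the differences (sample SD); their normal-theory CIs use
    +/- t * sd * sqrt(3/n), and the bias CI +/- t * sd / sqrt(n).  The
    paired t-test checks mean difference zero.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1:
        raise ValueError("observed and predicted must be equal-length 1-d arrays")
    n = observed.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(observed) == 0 or np.std(predicted) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(observed, predicted)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    diff = predicted - observed
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    tq = stats.t.ppf(1 - alpha / 2, n - 1)
    bias_half = tq * sd / np.sqrt(n)
    loa_half = tq * sd * np.sqrt(3.0 / n)
    z = stats.norm.ppf(0.975)  # 1.96 by construction of the limits
    loa_low, loa_high = bias - z * sd, bias + z * sd
    ttest = stats.ttest_rel(predicted, observed)
    return AgreementReport(
        n=n,
        pearson_r=float(res.statistic),
        r_ci=(float(ci.low), float(ci.high)),
        r_pvalue=float(res.pvalue),
        bias=bias,
        bias_ci=(bias - bias_half, bias + bias_half),
        bias_pvalue=float(ttest.pvalue),
        sd_diff=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        loa_low_ci=(loa_low - loa_half, loa_low + loa_half),
        loa_high_ci=(loa_high - loa_half, loa_high + loa_half),
    )
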