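"""Model evaluation: OOB metrics, random 10-fold CV, spatial (leave-monitors-out) CV.

Two cross-validation schemes are provided.  *Random* CV partitions rows;
it measures interpolation skill at monitored locations.  *Spatial* CV
partitions monitors, so every row of a held-out monitor leaves the training
set together; it measures the harder task of predicting where no monitor
exists.  Pooled metrics are computed over the concatenation of all test-fold
predictions, not averaged across folds.

Two leakage guards are enforced on every run: a monitor never appears in
both the training and test side of any spatial fold, and synthetic
(oversampled) rows may train but are never scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import FittedForest, ForestConfig, train_forest
from .smote import SmoteConfig, identify_minority, smote

__all__ = [
    "r2",
    "rmse",
    "CVReport",
    "kfold_cv",
    "spatial_kfold_cv",
    "oob_metrics",
    "oob_report",
]


def r2(obs, pred) -> float:
    """Coefficient of determination, ``1 - SSres/SStot`` (not squared
    correlation).  NaN when the observations are constant."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("obs and pred must share a length >= 2")
    sstot = np.sum((obs - obs.mean()) ** 2)
    if sstot == 0:
        return float("nan")
    ssres = np.sum((obs - pred) ** 2)
    return float(1.0 - ssres / sstot)


def rmse(obs, pred) -> float:
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.size < 1:
        raise ValueError("obs and pred must share a length >= 1")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


@dataclass
class CVReport:
    """Fold assignments plus pooled metrics.

    ``predictions`` holds one row per scored (real) observation with its
    fold, observation and prediction; ``per_fold`` carries per-fold test
    counts and MSEs so the pooled-RMSE identity can be checked.
    """

    scheme: str
    k: int
    fold_of_row: pd.Series
    fold_of_monitor: dict | None
    pooled_r2: float
    pooled_rmse: float
    per_fold: pd.DataFrame
    predictions: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "k": self.k,
            "pooled_r2": self.pooled_r2,
            "pooled_rmse": self.pooled_rmse,
            "fold_sizes": self.per_fold["n_test"].tolist(),
        }


def _augment_train(train: pd.DataFrame, predictors, target, smote_config):
    """SMOTE inside the fold: oversample the training side only."""
    if smote_config is None:
        return train
    flags = identify_minority(train[target], smote_config.minority_threshold)
    if flags.sum() <= smote_config.k_neighbors:
        return train  # too few high rows in this fold to interpolate
    return smote(train, predictors, target, flags, smote_config)


def _run_folds(table, fold_of_row: pd.Series, scheme: str, k: int,
               forest_config: ForestConfig, smote_config) -> CVReport:
    frame, predictors, target = table.frame, table.predictors, table.target
    if "synthetic" in frame.columns and frame["synthetic"].any():
        raise ValueError("cross-validation expects a table of real rows only")
    preds = []
    per_fold = []
    for fold in range(k):
        test_idx = fold_of_row.index[fold_of_row == fold]
        train_idx = fold_of_row.index[fold_of_row != fold]
        train = frame.loc[train_idx]
        test = frame.loc[test_idx]
        # leakage guard: synthetic rows train, never score
        assert not test.get("synthetic", pd.Series(False, index=test.index)).any()
        train = _augment_train(train, predictors, target, smote_config)
        cfg = ForestConfig(n_trees=forest_config.n_trees, m_try=forest_config.m_try,
                           seed=forest_config.seed + fold, min_leaf=forest_config.min_leaf)
        forest = train_forest(train[predictors].to_numpy(float),
                              train[target].to_numpy(float), predictors, cfg)
        yhat = forest.predict_frame(test)
        obs = test[target].to_numpy(float)
        preds.append(pd.DataFrame({"row": test_idx, "fold": fold, "obs": obs, "pred": yhat}))
        per_fold.append({"fold": fold, "n_test": len(test),
                         "mse": float(np.mean((obs - yhat) ** 2)) if len(test) else np.nan})
    pooled = pd.concat(preds, ignore_index=True)
    return CVReport(
        scheme=scheme,
        k=k,
        fold_of_row=fold_of_row,
        fold_of_monitor=None,
        pooled_r2=r2(pooled["obs"], pooled["pred"]),
        pooled_rmse=rmse(pooled["obs"], pooled["pred"]),
        per_fold=pd.DataFrame(per_fold),
        predictions=pooled,
    )


def kfold_cv(table, k: int = 10, forest_config: ForestConfig | None = None,
             smote_config: SmoteConfig | None = None, seed: int = 0) -> CVReport:
    """Random row-level k-fold CV with near-equal fold sizes."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    frame = table.frame
    if len(frame) < k:
        raise ValueError(f"{len(frame)} rows cannot be split into {k} folds")
    forest_config = forest_config or ForestConfig()
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(frame))
    folds = np.empty(len(frame), dtype=int)
    folds[order] = np.arange(len(frame)) % k  # sizes differ by at most one
    fold_of_row = pd.Series(folds, index=frame.index)
    return _run_folds(table, fold_of_row, "random", k, forest_config, smote_config)


def spatial_kfold_cv(table, k: int = 10, forest_config: ForestConfig | None = None,
                     smote_config: SmoteConfig | None = None, seed: int = 0) -> CVReport:
    """Leave-monitors-out CV: monitors, not rows, are partitioned into k
    roughly equal groups, so test locations are entirely unseen in training."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    frame = table.frame
    if "monitor_id" not in frame.columns:
        raise ValueError("table lacks a monitor_id column required for spatial CV")
    monitors = pd.unique(frame["monitor_id"])
    if len(monitors) < k:
        raise ValueError(f"{len(monitors)} monitors cannot form {k} spatial folds")
    forest_config = forest_config or ForestConfig()
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(monitors)
    fold_of_monitor = {m: i % k for i, m in enumerate(shuffled)}
    fold_of_row = frame["monitor_id"].map(fold_of_monitor)
    # leakage guard: a monitor's rows all share one fold by construction
    for fold in range(k):
        train_m = set(frame.loc[fold_of_row != fold, "monitor_id"])
        test_m = set(frame.loc[fold_of_row == fold, "monitor_id"])
        assert not (train_m & test_m), "monitor leaked across a spatial fold"
    report = _run_folds(table, fold_of_row, "spatial", k, forest_config, smote_config)
    report.fold_of_monitor = fold_of_monitor
    return report


def oob_metrics(forest: FittedForest) -> tuple[float, float]:
    """(R2, RMSE) of OOB predictions on the forest's own training rows."""
    ok = ~np.isnan(forest.oob_prediction)
    if not ok.any():
        raise ValueError("no rows with defined OOB predictions")
    if forest.constant_target:
        return float("nan"), rmse(forest.y[ok], forest.oob_prediction[ok])
    return (r2(forest.y[ok], forest.oob_prediction[ok]),
            rmse(forest.y[ok], forest.oob_prediction[ok]))


def oob_report(forest: FittedForest, frame: pd.DataFrame, target: str) -> tuple[float, float]:
    """OOB (R2, RMSE) restricted to real rows with defined OOB predictions.

    ``frame`` must be the table the forest was trained on, in training row
    order; synthetic (oversampled) rows are excluded from the metrics.
    """
    if len(frame) != len(forest.y):
        raise ValueError("frame does not match the forest's training rows")
    real = ~frame.get("synthetic", pd.Series(False, index=frame.index)).to_numpy(bool)
    ok = real & ~np.isnan(forest.oob_prediction)
    if not ok.any():
        raise ValueError("no real rows with defined OOB predictions")
    obs = frame[target].to_numpy(float)[ok]
    pred = forest.oob_prediction[ok]
    if np.all(obs == obs[0]):
        return float("nan"), rmse(obs, pred)
    return r2(obs, pred), rmse(obs, pred)
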