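"""Bagged regression-tree ensembles with out-of-bag diagnostics.

Thin, deterministic wrapper around scikit-learn's RandomForestRegressor that
standardizes the two places the pipeline needs forests (satellite-AOD
gap-filling and the final PM2.5 model): per-row out-of-bag (OOB)
predictions, OOB R^2/RMSE, and permutation importance *measured on OOB
samples* so that importances are not inflated by in-bag memorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.ensemble._forest import (
    _generate_unsampled_indices,
    _get_n_samples_bootstrap,
)

__all__ = ["ForestConfig", "FittedForest", "train_forest"]


def _n_samples_bootstrap(n: int, max_samples) -> int:
    try:
        return _get_n_samples_bootstrap(n, max_samples, None)
    except TypeError:  # older signature without sample_weight
        return _get_n_samples_bootstrap(n, max_samples)


def _unsampled_indices(random_state, n: int, n_boot: int) -> np.ndarray:
    try:
        return _generate_unsampled_indices(random_state, n, n_boot, None)
    except TypeError:
        return _generate_unsampled_indices(random_state, n, n_boot)


@dataclass(frozen=True)
class ForestConfig:
    """Ensemble hyperparameters: 500 trees with 4 candidate split variables,
    the values tuned for the hourly gap-filling stage and reused for the
    PM2.5 stage; ``min_leaf=5`` is the customary regression leaf size."""

    n_trees: int = 500
    m_try: int = 4
    seed: int = 0
    min_leaf: int = 5

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError(f"n_trees must be >= 1, got {self.n_trees}")
        if self.m_try < 1:
            raise ValueError(f"m_try must be >= 1, got {self.m_try}")
        if self.min_leaf < 1:
            raise ValueError(f"min_leaf must be >= 1, got {self.min_leaf}")


@dataclass
class FittedForest:
    """A trained ensemble plus its training matrix and OOB artifacts.

    ``oob_prediction`` is NaN for rows that were in-bag for every tree;
    ``constant_target`` flags a degenerate fit whose OOB R^2 is undefined.
    """

    estimator: RandomForestRegressor
    predictor_names: list[str]
    X: np.ndarray
    y: np.ndarray
    oob_prediction: np.ndarray
    constant_target: bool
    _perm_importance: pd.Series | None = field(default=None, repr=False)

    @property
    def n_predictors(self) -> int:
        return len(self.predictor_names)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_predictors:
            raise ValueError(
                f"predictor count {X.shape[1]} != training count {self.n_predictors}"
            )
        return self.estimator.predict(X)

    def predict_frame(self, frame: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.predictor_names if c not in frame.columns]
        if missing:
            raise ValueError(f"frame lacks predictors {missing}")
        return self.predict(frame[self.predictor_names].to_numpy(dtype=float))

    @property
    def impurity_importance(self) -> pd.Series:
        return pd.Series(self.estimator.feature_importances_, index=self.predictor_names)

    def oob_permutation_importance(self, seed: int = 0) -> pd.Series:
        """Permutation importance evaluated on each tree's OOB rows.

        For every predictor, the column is shuffled once (a single shared
        permutation) and OOB predictions are recomputed tree by tree; the
        importance is the resulting increase in OOB MSE, floored at zero and
        normalized to sum to one.
        """
        if self._perm_importance is not None:
            return self._perm_importance
        est, X, y = self.estimator, self.X, self.y
        n = len(y)
        n_boot = _n_samples_bootstrap(n, est.max_samples)
        oob_sets = [
            _unsampled_indices(tree.random_state, n, n_boot)
            for tree in est.estimators_
        ]
        valid = ~np.isnan(self.oob_prediction)
        base_mse = float(np.mean((self.oob_prediction[valid] - y[valid]) ** 2))
        rng = np.random.default_rng(seed)
        scores = np.zeros(self.n_predictors)
        for j in range(self.n_predictors):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(n), j]
            pred_sum = np.zeros(n)
            cnt = np.zeros(n)
            for tree, oob in zip(est.estimators_, oob_sets):
                if len(oob) == 0:
                    continue
                pred_sum[oob] += tree.predict(Xp[oob])
                cnt[oob] += 1
            ok = cnt > 0
            mse_j = float(np.mean((pred_sum[ok] / cnt[ok] - y[ok]) ** 2))
            scores[j] = max(mse_j - base_mse, 0.0)
        total = scores.sum()
        if total > 0:
            scores = scores / total
        self._perm_importance = pd.Series(scores, index=self.predictor_names)
        return self._perm_importance


def train_forest(X, y, predictor_names: list[str], config: ForestConfig) -> FittedForest:
    """Fit a bagged regression-tree ensemble with OOB bookkeeping.

    Deterministic given ``config.seed``.  A constant target is fitted but
    flagged (its OOB R^2 is undefined); ``m_try`` is clipped to the number
    of predictors.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per target value")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("training table contains missing values")
    if X.shape[1] != len(predictor_names):
        raise ValueError("predictor_names length does not match X columns")
    constant = bool(np.all(y == y[0]))
    est = RandomForestRegressor(
        n_estimators=config.n_trees,
        max_features=min(config.m_try, X.shape[1]),
        min_samples_leaf=config.min_leaf,
        bootstrap=True,
        oob_score=False,  # per-row OOB predictions assembled below
        random_state=config.seed,
        n_jobs=1,
    )
    est.fit(X, y)
    n = len(y)
    n_boot = _n_samples_bootstrap(n, est.max_samples)
    pred_sum = np.zeros(n)
    cnt = np.zeros(n)
    for tree in est.estimators_:
        oob = _unsampled_indices(tree.random_state, n, n_boot)
        if len(oob) == 0:
            continue
        pred_sum[oob] += tree.predict(X[oob])
        cnt[oob] += 1
    oob_pred = np.full(n, np.nan)
    ok = cnt > 0
    oob_pred[ok] = pred_sum[ok] / cnt[ok]
    return FittedForest(
        estimator=est,
        predictor_names=list(predictor_names),
        X=X,
        y=y,
        oob_prediction=oob_pred,
        constant_target=constant,
    )
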