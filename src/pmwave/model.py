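"""The hourly PM2.5 prediction model (Model / Results idiom).

:class:`PM25Model` holds a training table of (cell, hour) monitor rows --
wavelet and raw features from the gap-filled AOD and meteorology, target
PM2.5 -- plus the ensemble and oversampling configurations.  ``fit()``
oversamples the high-concentration tail (when configured), trains one
pooled random forest across all hours, and returns a :class:`PM25Results`
carrying OOB diagnostics, importances, cross-validation drivers, and
surface prediction.

Ground PM2.5 enters only as the target: no predictor is derived from the
monitor measurements, so the fitted model can render a surface at every
grid cell, monitored or not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import FittedForest, ForestConfig, train_forest
from .features import FeatureSpec, assemble_features, default_feature_spec
from .grid import Field, GridSpec, merge_observations
from .smote import SmoteConfig, identify_minority, smote
from .validation import CVReport, kfold_cv, oob_report, spatial_kfold_cv

__all__ = [
    "TrainingTable",
    "build_training_table",
    "train_pm25",
    "predict_surface",
    "PM25Model",
    "PM25Results",
]


@dataclass
class TrainingTable:
    """(cell, hour) rows of predictors and target PM2.5.

    ``frame`` carries the predictor columns named by the feature spec plus
    bookkeeping: ``cell, hour, monitor_id, source, synthetic, pm25``.
    ``monitor_id`` identifies the monitored cell and drives spatial CV.
    """

    frame: pd.DataFrame
    predictors: list[str]
    target: str = "pm25"

    def __post_init__(self):
        missing = [c for c in self.predictors + [self.target] if c not in self.frame.columns]
        if missing:
            raise ValueError(f"table lacks columns {missing}")
        if "synthetic" not in self.frame.columns:
            self.frame = self.frame.copy()
            self.frame["synthetic"] = False
        bad = self.frame[self.predictors].isna().any(axis=1)
        if bad.any():
            raise ValueError(f"{int(bad.sum())} rows have missing predictors")

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def X(self) -> np.ndarray:
        return self.frame[self.predictors].to_numpy(float)

    def y(self) -> np.ndarray:
        return self.frame[self.target].to_numpy(float)

    def real_only(self) -> "TrainingTable":
        return TrainingTable(self.frame[~self.frame["synthetic"]].reset_index(drop=True),
                             self.predictors, self.target)


def build_training_table(filled_aod: list[Field], met: dict[str, list[Field]],
                         observations: pd.DataFrame, spec: FeatureSpec) -> TrainingTable:
    """Assemble the pooled training table over all hours.

    Per hour: monitor records are collapsed to one value per cell (reference
    monitors override low-cost ones), features are read at those cells from
    the hour's component rasters, and rows are stacked.  Hours whose AOD
    still has gaps (e.g. no retrievals to train a gap-fill) are skipped and
    counted in ``frame.attrs["skipped_hours"]``.
    """
    grid = filled_aod[0].grid
    rows = []
    skipped = []
    for h, aod in enumerate(filled_aod):
        if aod.missing.any():
            skipped.append(h)
            continue
        met_h = {v: flds[h] for v, flds in met.items()}
        obs_h = observations[observations["hour"] == h]
        if obs_h.empty:
            continue
        merged = merge_observations(obs_h, grid, hour=h)
        if merged.empty:
            continue
        cells = merged["cell"].to_numpy(int)
        feats = assemble_features(aod, met_h, spec, cells=cells)
        feats.insert(0, "cell", cells)
        feats.insert(1, "hour", h)
        feats.insert(2, "monitor_id", cells)  # one merged monitor per cell
        feats.insert(3, "source", merged["source"].to_numpy())
        feats["pm25"] = merged["pm25"].to_numpy(float)
        rows.append(feats)
    if not rows:
        raise ValueError("no usable (hour, monitor) rows to train on")
    frame = pd.concat(rows, ignore_index=True)
    frame["synthetic"] = False
    frame.attrs["skipped_hours"] = skipped
    return TrainingTable(frame, predictors=spec.column_names())


def train_pm25(table: TrainingTable, config: ForestConfig) -> FittedForest:
    """One pooled ensemble across all hours (only gap-filling is per-hour)."""
    if table.n_rows < 100:
        raise ValueError(f"PM2.5 table has {table.n_rows} rows; need >= 100")
    return train_forest(table.X(), table.y(), table.predictors, config)


def predict_surface(forest: FittedForest, filled_aod: Field, met: dict[str, Field],
                    spec: FeatureSpec) -> Field:
    """Render the PM2.5 surface for one hour: a value at every cell, no gaps."""
    if forest.predictor_names != spec.column_names():
        raise ValueError("forest was not trained on the columns of this feature spec")
    feats = assemble_features(filled_aod, met, spec, cells=None)
    pred = forest.predict_frame(feats)
    grid = filled_aod.grid
    return Field(grid=grid, variable="pm25_pred", hour=filled_aod.hour,
                 values=pred.reshape(grid.n_rows, grid.n_cols),
                 missing=np.zeros((grid.n_rows, grid.n_cols), dtype=bool))


@dataclass
class PM25Model:
    """Pooled hourly PM2.5 model over a training table."""

    table: TrainingTable
    feature_spec: FeatureSpec = field(default_factory=default_feature_spec)
    forest_config: ForestConfig = field(default_factory=ForestConfig)
    smote_config: SmoteConfig | None = field(default_factory=SmoteConfig)

    @classmethod
    def from_fields(cls, filled_aod: list[Field], met: dict[str, list[Field]],
                    observations: pd.DataFrame, feature_spec: FeatureSpec | None = None,
                    forest_config: ForestConfig | None = None,
                    smote_config: SmoteConfig | None = SmoteConfig()) -> "PM25Model":
        spec = feature_spec or default_feature_spec()
        table = build_training_table(filled_aod, met, observations, spec)
        return cls(table=table, feature_spec=spec,
                   forest_config=forest_config or ForestConfig(),
                   smote_config=smote_config)

    def _augmented(self) -> TrainingTable:
        table = self.table
        if self.smote_config is None:
            return table
        flags = identify_minority(table.y(), self.smote_config.minority_threshold)
        if flags.sum() <= self.smote_config.k_neighbors:
            return table
        frame = smote(table.frame, table.predictors, table.target, flags, self.smote_config)
        return TrainingTable(frame, table.predictors, table.target)

    def fit(self) -> "PM25Results":
        augmented = self._augmented()
        forest = train_pm25(augmented, self.forest_config)
        return PM25Results(model=self, augmented=augmented, forest=forest)

    def cross_validate(self, scheme: str = "random", k: int = 10, seed: int = 0,
                       forest_config: ForestConfig | None = None) -> CVReport:
        """Cross-validate the *real* table; oversampling happens inside each
        training fold, never before splitting."""
        cfg = forest_config or self.forest_config
        real = self.table.real_only()
        if scheme == "random":
            return kfold_cv(real, k=k, forest_config=cfg,
                            smote_config=self.smote_config, seed=seed)
        if scheme == "spatial":
            return spatial_kfold_cv(real, k=k, forest_config=cfg,
                                    smote_config=self.smote_config, seed=seed)
        raise ValueError(f"unknown CV scheme {scheme!r}; use 'random' or 'spatial'")


@dataclass
class PM25Results:
    model: PM25Model
    augmented: TrainingTable
    forest: FittedForest

    @property
    def oob_r2(self) -> float:
        return oob_report(self.forest, self.augmented.frame, self.augmented.target)[0]

    @property
    def oob_rmse(self) -> float:
        return oob_report(self.forest, self.augmented.frame, self.augmented.target)[1]

    @property
    def importances(self) -> pd.Series:
        """Impurity importances (cheap); use
        ``forest.oob_permutation_importance()`` for the pruning measure."""
        return self.forest.impurity_importance

    def predict_surface(self, filled_aod: Field, met: dict[str, Field]) -> Field:
        return predict_surface(self.forest, filled_aod, met, self.model.feature_spec)

    def cross_validate(self, scheme: str = "random", k: int = 10, seed: int = 0) -> CVReport:
        return self.model.cross_validate(scheme=scheme, k=k, seed=seed)

    def summary(self) -> str:
        n_real = int((~self.augmented.frame["synthetic"]).sum())
        n_syn = int(self.augmented.frame["synthetic"].sum())
        cfg = self.model.forest_config
        top = self.importances.sort_values(ascending=False).head(8)
        lines = [
            "Hourly PM2.5 ensemble model",
            "=" * 42,
            f"training rows:        {n_real} real + {n_syn} synthetic",
            f"predictors:           {self.forest.n_predictors}",
            f"trees / m_try / leaf: {cfg.n_trees} / {cfg.m_try} / {cfg.min_leaf}",
            f"OOB R2 (real rows):   {self.oob_r2:.4f}",
            f"OOB RMSE (real rows): {self.oob_rmse:.3f} ug/m3",
            "-" * 42,
            "top predictors (impurity importance):",
        ]
        for name, val in top.items():
            lines.append(f"  {name:<24s} {val:.4f}")
        return "\n".join(lines)
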