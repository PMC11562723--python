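"""Per-hour ensemble gap-filling of satellite AOD.

Satellite AOD retrievals are missing wherever clouds (or bright surfaces)
block the retrieval.  For each hour, the observed cells form a training set
whose predictors are the gap-free background-model AOD and the
meteorological fields at the same cells; a bagged regression-tree ensemble
learns the mapping and predicts AOD in the gap cells.  Observed retrievals
are never altered -- the filled field equals the satellite field bitwise
wherever a retrieval exists.

Hours with zero successful retrievals cannot be filled and are skipped by
the scene-level driver (and counted in its log).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import FittedForest, ForestConfig, train_forest
from .grid import Field
from .validation import oob_metrics

__all__ = [
    "build_gapfill_table",
    "train_gapfill",
    "fill_gaps",
    "GapFillModel",
    "GapFillResults",
    "fill_scene",
]


def _predictor_frame(background_aod: Field, met: dict[str, Field], cells: np.ndarray):
    cols = {"background_aod": background_aod.values.reshape(-1)[cells]}
    for var, f in met.items():
        cols[var] = f.values.reshape(-1)[cells]
    return pd.DataFrame(cols)


def build_gapfill_table(satellite_aod: Field, background_aod: Field,
                        met: dict[str, Field]) -> pd.DataFrame:
    """One row per observed satellite cell: predictors + target ``aod``.

    Rows with any missing predictor are dropped; the drop count is recorded
    in ``frame.attrs["n_dropped"]``.  Raises when the hour has no observed
    cells at all (such hours are excluded from the analysis).
    """
    grid = satellite_aod.grid
    for name, f in {"background_aod": background_aod, **met}.items():
        if f.grid != grid:
            raise ValueError(f"field {name!r} on a different grid than the satellite AOD")
    observed = ~satellite_aod.missing.reshape(-1)
    if not observed.any():
        raise ValueError(
            f"hour {satellite_aod.hour!r} has zero observed AOD cells and cannot be filled"
        )
    cells = np.flatnonzero(observed)
    frame = _predictor_frame(background_aod, met, cells)
    frame.insert(0, "cell", cells)
    frame["aod"] = satellite_aod.values.reshape(-1)[cells]
    good = ~frame.drop(columns="cell").isna().any(axis=1)
    n_dropped = int((~good).sum())
    frame = frame[good].reset_index(drop=True)
    frame.attrs["n_dropped"] = n_dropped
    return frame


def train_gapfill(table: pd.DataFrame, config: ForestConfig) -> FittedForest:
    """Fit the per-hour gap-filling ensemble on the observed-cell table."""
    if len(table) < 50:
        raise ValueError(f"gap-fill table has {len(table)} rows; need >= 50")
    predictors = [c for c in table.columns if c not in ("cell", "aod")]
    return train_forest(table[predictors].to_numpy(float),
                        table["aod"].to_numpy(float), predictors, config)


def fill_gaps(model: FittedForest, satellite_aod: Field, background_aod: Field,
              met: dict[str, Field]) -> Field:
    """Fill every gap cell with the model prediction; keep retrievals verbatim."""
    expected = ["background_aod"] + list(met.keys())
    if model.predictor_names != expected:
        raise ValueError(
            f"model predictors {model.predictor_names} != supplied {expected}"
        )
    out = satellite_aod.copy()
    gaps = np.flatnonzero(satellite_aod.missing.reshape(-1))
    if len(gaps):
        Xgap = _predictor_frame(background_aod, met, gaps)
        pred = model.predict_frame(Xgap)
        flat = out.values.reshape(-1)
        flat[gaps] = pred
        out.values = flat.reshape(out.values.shape)
        out.missing = np.zeros_like(out.missing)
    return out


@dataclass
class GapFillModel:
    """Model object for one hour's AOD gap-fill (fit/Results idiom).

    Parameters are the hour's satellite AOD field (with gaps), the gap-free
    background-model AOD, and the meteorological fields; ``fit`` trains the
    ensemble on the observed cells and returns a :class:`GapFillResults`.
    """

    satellite_aod: Field
    background_aod: Field
    met: dict[str, Field]
    config: ForestConfig = field(default_factory=ForestConfig)

    def fit(self) -> "GapFillResults":
        table = build_gapfill_table(self.satellite_aod, self.background_aod, self.met)
        forest = train_gapfill(table, self.config)
        return GapFillResults(model=self, table=table, forest=forest)


@dataclass
class GapFillResults:
    model: GapFillModel
    table: pd.DataFrame
    forest: FittedForest

    @property
    def oob_r2(self) -> float:
        return oob_metrics(self.forest)[0]

    @property
    def oob_rmse(self) -> float:
        return oob_metrics(self.forest)[1]

    def filled(self) -> Field:
        return fill_gaps(self.forest, self.model.satellite_aod,
                         self.model.background_aod, self.model.met)

    def summary(self) -> str:
        lines = [
            "Gap-fill ensemble (one hour)",
            "=" * 34,
            f"hour:            {self.model.satellite_aod.hour!r}",
            f"observed cells:  {len(self.table)}",
            f"gap cells:       {self.model.satellite_aod.n_missing}",
            f"dropped rows:    {self.table.attrs.get('n_dropped', 0)}",
            f"trees / m_try:   {self.model.config.n_trees} / {self.model.config.m_try}",
            f"OOB R2:          {self.oob_r2:.4f}",
            f"OOB RMSE:        {self.oob_rmse:.4f} (AOD)",
        ]
        return "\n".join(lines)


def fill_scene(masked_aod: list[Field], background_aod: list[Field],
               met: dict[str, list[Field]], config: ForestConfig):
    """Gap-fill every hour of a scene with a separate hourly model.

    Hours without a single retrieval are skipped (left as-is) and listed in
    the returned log, mirroring their exclusion from the downstream model.

    Returns ``(filled_fields, log)`` where ``log`` has per-hour OOB metrics
    and counts.
    """
    filled: list[Field] = []
    log = {"hours": [], "skipped_hours": []}
    for h, sat in enumerate(masked_aod):
        met_h = {v: flds[h] for v, flds in met.items()}
        if (~sat.missing).sum() == 0:
            log["skipped_hours"].append(h)
            filled.append(sat.copy())
            continue
        res = GapFillModel(sat, background_aod[h], met_h,
                           ForestConfig(n_trees=config.n_trees, m_try=config.m_try,
                                        seed=config.seed + h, min_leaf=config.min_leaf)).fit()
        filled.append(res.filled())
        log["hours"].append({
            "hour": h,
            "n_observed": len(res.table),
            "n_gaps": sat.n_missing,
            "oob_r2": res.oob_r2,
            "oob_rmse": res.oob_rmse,
        })
    return filled, log
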