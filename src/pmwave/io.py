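"""File formats, configuration, and the end-to-end pipeline driver.

Gridded fields travel as classic NetCDF (one variable per field, dimensions
``hour, y, x``, grid geometry in global attributes, gaps encoded as NaN);
monitor observations as CSV with columns ``site_id, source, x, y, hour,
pm25``; configuration and reports as JSON.  ``run_pipeline`` chains the
stages -- simulate, cloud-mask, gap-fill, feature assembly, oversampled
training, cross-validation, surface prediction -- and writes its artifacts
plus a log of row counts, seeds and versions, so a run is reproducible from
its config file alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import __version__ as _pkg_version
from .ensemble import ForestConfig
from .features import FeatureSpec, default_feature_spec
from .gapfill import fill_scene
from .grid import Field, GridSpec
from .model import PM25Model
from .scene import SceneConfig, apply_cloud_mask, place_sites, sample_observations, simulate_fields
from .smote import SmoteConfig

__all__ = [
    "write_fields",
    "read_fields",
    "read_field",
    "write_observations",
    "read_observations",
    "PipelineConfig",
    "run_pipeline",
]

_GRID_ATTRS = ("origin_x", "origin_y", "cell_size")


def _grid_of(ds: xr.Dataset) -> GridSpec:
    missing = [a for a in _GRID_ATTRS if a not in ds.attrs]
    if missing:
        raise ValueError(f"file lacks grid metadata attributes {missing}")
    return GridSpec(
        origin_x=float(ds.attrs["origin_x"]),
        origin_y=float(ds.attrs["origin_y"]),
        cell_size=float(ds.attrs["cell_size"]),
        n_rows=ds.sizes["y"],
        n_cols=ds.sizes["x"],
    )


def write_fields(path, fields: dict[str, list[Field]]) -> None:
    """Write per-hour fields of several variables to one NetCDF file.

    All fields must share a grid; hours become a dimension; missing cells
    are stored as NaN (the mask is reconstructed on read).
    """
    first = next(iter(fields.values()))[0]
    grid = first.grid
    n_hours = len(next(iter(fields.values())))
    data_vars = {}
    for var, flds in fields.items():
        if len(flds) != n_hours:
            raise ValueError(f"variable {var!r} has {len(flds)} hours, expected {n_hours}")
        stack = np.empty((n_hours, grid.n_rows, grid.n_cols))
        for h, f in enumerate(flds):
            if f.grid != grid:
                raise ValueError(f"field {var!r} hour {h} on a different grid")
            stack[h] = np.where(f.missing, np.nan, f.values)
        data_vars[var] = (("hour", "y", "x"), stack)
    ds = xr.Dataset(
        data_vars,
        coords={
            "hour": np.arange(n_hours),
            "y": grid.y_centers(),
            "x": grid.x_centers(),
        },
        attrs={
            "origin_x": grid.origin_x,
            "origin_y": grid.origin_y,
            "cell_size": grid.cell_size,
            "creator": f"pmwave {_pkg_version}",
        },
    )
    ds.to_netcdf(path, engine="scipy")


def read_fields(path, expected_grid: GridSpec | None = None) -> dict[str, list[Field]]:
    """Read every variable back as per-hour fields (inverse of write_fields)."""
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
    grid = _grid_of(ds)
    if expected_grid is not None and grid != expected_grid:
        raise ValueError(f"grid in file ({grid}) != expected grid ({expected_grid})")
    out: dict[str, list[Field]] = {}
    for var in ds.data_vars:
        flds = []
        for h in range(ds.sizes["hour"]):
            vals = np.asarray(ds[var].isel(hour=h).values, dtype=float)
            flds.append(Field(grid=grid, variable=str(var), hour=h, values=vals,
                              missing=np.isnan(vals)))
        out[str(var)] = flds
    return out


def read_field(path, variable: str, hour: int,
               expected_grid: GridSpec | None = None) -> Field:
    fields = read_fields(path, expected_grid)
    if variable not in fields:
        raise KeyError(f"variable {variable!r} not in {sorted(fields)}")
    return fields[variable][hour]


def write_observations(path, records: pd.DataFrame) -> None:
    records.to_csv(path, index=False)


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    needed = {"site_id", "source", "x", "y", "hour", "pm25"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"observations file lacks columns {sorted(missing)}")
    return df


def _from_mapping(cls, mapping: dict, where: str):
    """Build a dataclass from a JSON mapping, rejecting unknown keys."""
    allowed = {f.name for f in dc_fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown keys {sorted(unknown)} in {where}")
    kwargs = dict(mapping)
    for f in dc_fields(cls):  # JSON arrays -> tuples where the field expects one
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


@dataclass
class PipelineConfig:
    """Everything a run needs; serializes to/from JSON losslessly."""

    seed: int = 0
    scene: SceneConfig | None = field(default_factory=SceneConfig)
    fields_path: str | None = None  # alternative to simulation
    observations_path: str | None = None
    gapfill_forest: ForestConfig = field(default_factory=ForestConfig)
    pm25_forest: ForestConfig = field(default_factory=ForestConfig)
    smote: SmoteConfig | None = field(default_factory=SmoteConfig)
    cv_scheme: str = "random"
    cv_k: int = 10
    surface_hours: tuple = (0,)
    write_scene: bool = False

    _TOP_KEYS = ("seed", "scene", "fields_path", "observations_path",
                 "gapfill_forest", "pm25_forest", "smote", "cv_scheme",
                 "cv_k", "surface_hours", "write_scene")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        unknown = set(raw) - set(cls._TOP_KEYS)
        if unknown:
            raise ValueError(f"unknown keys {sorted(unknown)} in pipeline config")
        kwargs = {}
        for key in ("seed", "fields_path", "observations_path", "cv_scheme",
                    "cv_k", "write_scene"):
            if key in raw:
                kwargs[key] = raw[key]
        if "surface_hours" in raw:
            kwargs["surface_hours"] = tuple(raw["surface_hours"])
        if "scene" in raw:
            kwargs["scene"] = (None if raw["scene"] is None
                               else _from_mapping(SceneConfig, raw["scene"], "scene"))
        for key, klass in (("gapfill_forest", ForestConfig), ("pm25_forest", ForestConfig)):
            if key in raw:
                kwargs[key] = _from_mapping(klass, raw[key], key)
        if "smote" in raw:
            kwargs["smote"] = (None if raw["smote"] is None
                               else _from_mapping(SmoteConfig, raw["smote"], "smote"))
        return cls(**kwargs)

    def to_json(self, path) -> None:
        out = {
            "seed": self.seed,
            "scene": None if self.scene is None else asdict(self.scene),
            "fields_path": self.fields_path,
            "observations_path": self.observations_path,
            "gapfill_forest": asdict(self.gapfill_forest),
            "pm25_forest": asdict(self.pm25_forest),
            "smote": None if self.smote is None else asdict(self.smote),
            "cv_scheme": self.cv_scheme,
            "cv_k": self.cv_k,
            "surface_hours": list(self.surface_hours),
            "write_scene": self.write_scene,
        }
        Path(path).write_text(json.dumps(out, indent=2))


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full workflow and write artifacts under ``outdir``.

    simulate (or load) -> cloud-mask -> per-hour gap-fill -> wavelet feature
    assembly at monitor cells -> oversample + train -> cross-validate ->
    render gap-free surfaces.  Returns the log dictionary (also written as
    ``log.json``); any stage failure raises with the stage named.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"version": _pkg_version, "seed": config.seed, "stages": {}}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as err:
                raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        return wrap

    if config.scene is not None:
        def _simulate():
            scene_cfg = config.scene
            truth = simulate_fields(scene_cfg)
            sites = place_sites(scene_cfg, seed=config.seed + 1)
            obs = sample_observations(truth, sites, seed=config.seed + 2)
            masked = [
                apply_cloud_mask(f, scene_cfg.gap_fraction, scene_cfg.blob_scale,
                                 seed=config.seed + 100 + h)
                for h, f in enumerate(truth.true_aod)
            ]
            log["stages"]["simulate"] = {
                "n_hours": truth.n_hours,
                "theoretical_r2": truth.theoretical_r2,
                "noise_sd": truth.noise_sd,
                "n_sites": len(sites),
                "seeds": {"scene": scene_cfg.seed, "sites": config.seed + 1,
                          "observations": config.seed + 2,
                          "cloud_mask_base": config.seed + 100},
                "masked_cells_per_hour": [f.n_missing for f in masked],
            }
            return truth, obs, masked
        truth, observations, masked = stage("simulate")(_simulate)
        background = truth.background_aod
        met = truth.met
        if config.write_scene:
            write_fields(outdir / "scene.nc", {
                "true_aod": truth.true_aod,
                "background_aod": background,
                "true_pm25": truth.true_pm25,
                **truth.met,
            })
            write_observations(outdir / "observations.csv", observations)
    else:
        def _load():
            if not config.fields_path or not config.observations_path:
                raise ValueError("without a scene, fields_path and observations_path are required")
            fields = read_fields(config.fields_path)
            obs = read_observations(config.observations_path)
            masked = fields.pop("satellite_aod")
            background = fields.pop("background_aod")
            log["stages"]["load"] = {"n_hours": len(masked), "n_records": len(obs)}
            return masked, background, fields, obs
        masked, background, met, observations = stage("load")(_load)

    def _gapfill():
        filled, gf_log = fill_scene(masked, background, met, config.gapfill_forest)
        log["stages"]["gapfill"] = {
            "hours_filled": len(gf_log["hours"]),
            "hours_skipped_no_retrievals": gf_log["skipped_hours"],
            "mean_oob_r2": (float(np.mean([h["oob_r2"] for h in gf_log["hours"]]))
                            if gf_log["hours"] else None),
            "per_hour": gf_log["hours"],
        }
        return filled
    filled = stage("gapfill")(_gapfill)

    def _train():
        spec = default_feature_spec()
        pm = PM25Model.from_fields(filled, met, observations, feature_spec=spec,
                                   forest_config=config.pm25_forest,
                                   smote_config=config.smote)
        results = pm.fit()
        n_syn = int(results.augmented.frame["synthetic"].sum())
        log["stages"]["train"] = {
            "rows_real": pm.table.n_rows,
            "rows_synthetic": n_syn,
            "rows_by_source": pm.table.frame["source"].value_counts().to_dict(),
            "skipped_hours": pm.table.frame.attrs.get("skipped_hours", []),
            "oob_r2": results.oob_r2,
            "oob_rmse": results.oob_rmse,
        }
        return pm, results
    pm, results = stage("train")(_train)

    def _validate():
        report = pm.cross_validate(scheme=config.cv_scheme, k=config.cv_k,
                                   seed=config.seed)
        log["stages"]["validate"] = report.to_dict()
        (outdir / "cv_report.json").write_text(json.dumps(report.to_dict(), indent=2))
        return report
    stage("validate")(_validate)

    def _predict():
        surfaces = []
        for h in config.surface_hours:
            met_h = {v: flds[h] for v, flds in met.items()}
            surfaces.append(results.predict_surface(filled[h], met_h))
        write_fields(outdir / "pm25_surface.nc", {"pm25_pred": surfaces})
        log["stages"]["predict"] = {
            "hours": list(config.surface_hours),
            "missing_cells": [int(s.n_missing) for s in surfaces],
        }
    stage("predict")(_predict)

    (outdir / "log.json").write_text(json.dumps(log, indent=2, default=float))
    return log
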