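"""Wavelet + raw feature assembly and importance-based pruning.

A :class:`FeatureSpec` maps each gridded variable to the subset of signal
components it contributes: the raw field, the scale-J wavelet approximation
``l_J``, and/or detail bands ``h_1..h_J``.  Feature assembly decomposes each
selected variable's full-grid field once per hour (row-major, Daubechies
filters from :mod:`pmwave.wavelets`) and reads the selected component
rasters at the requested cells, in a fixed, recorded column order.

The default specification is the selection retained by the final PM2.5
model: all six AOD components; the low-frequency component only for
longwave flux, u-wind, surface pressure, boundary-layer height and specific
humidity; ``h_1, h_3, l_5`` for upward shortwave flux; raw values for 2 m
temperature, v-wind, downward shortwave flux and relative humidity; plus
the planar cell-center coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grid import Field, GridSpec
from .wavelets import daubechies_filters, max_decomposition_level, mra_components

__all__ = ["FeatureSpec", "default_feature_spec", "assemble_features", "prune_by_importance"]

_RAW = "raw"


def _canonical_order(J: int) -> list[str]:
    return [_RAW, f"l_{J}"] + [f"h_{j}" for j in range(1, J + 1)]


@dataclass(frozen=True)
class FeatureSpec:
    """Per-variable component selection for the prediction model."""

    components: dict[str, tuple[str, ...]]
    J: int = 5
    include_coordinates: bool = True
    wavelet_order: int = 5
    extension_mode: str = "symmetric"

    def __post_init__(self):
        valid = set(_canonical_order(self.J))
        n_features = 0
        for var, comps in self.components.items():
            if not comps:
                raise ValueError(f"variable {var!r} selects no components")
            for c in comps:
                if c not in valid:
                    raise ValueError(f"component {c!r} of {var!r} not valid for J={self.J}")
            n_features += len(comps)
        if n_features + (2 if self.include_coordinates else 0) == 0:
            raise ValueError("feature spec selects no features at all")

    def needs_decomposition(self, var: str) -> bool:
        return any(c != _RAW for c in self.components[var])

    def column_names(self) -> list[str]:
        """Fixed column order: variables in spec order, components in
        canonical order (raw, l_J, h_1..h_J), coordinates last."""
        names = []
        order = _canonical_order(self.J)
        for var, comps in self.components.items():
            for c in sorted(comps, key=order.index):
                names.append(var if c == _RAW else f"{var}_{c}")
        if self.include_coordinates:
            names += ["coord_x", "coord_y"]
        return names

    @property
    def n_features(self) -> int:
        return len(self.column_names())


def default_feature_spec() -> FeatureSpec:
    """The retained predictor set of the final model (20 columns)."""
    J = 5
    return FeatureSpec(
        components={
            "aod": (f"l_{J}", "h_1", "h_2", "h_3", "h_4", "h_5"),
            "longwave": (f"l_{J}",),
            "wind_u": (f"l_{J}",),
            "surface_pressure": (f"l_{J}",),
            "pblh": (f"l_{J}",),
            "specific_humidity": (f"l_{J}",),
            "shortwave_up": ("h_1", "h_3", f"l_{J}"),
            "temperature_2m": (_RAW,),
            "wind_v": (_RAW,),
            "shortwave_down": (_RAW,),
            "relative_humidity": (_RAW,),
        },
        J=J,
        include_coordinates=True,
    )


def raw_only_spec(spec: FeatureSpec) -> FeatureSpec:
    """The ablation twin of ``spec``: same variables, raw values only."""
    return replace(
        spec,
        components={var: (_RAW,) for var in spec.components},
    )


def assemble_features(
    filled_aod: Field,
    met: dict[str, Field],
    spec: FeatureSpec,
    cells: np.ndarray | None = None,
) -> pd.DataFrame:
    """Predictor matrix for one hour, at ``cells`` (flat indices) or all cells.

    Each variable needing wavelet components is decomposed exactly once on
    the full grid; component values are then read off at the requested
    cells.  Raises if a selected variable has no field or any field still
    has gaps.
    """
    fields = {"aod": filled_aod, **met}
    grid = filled_aod.grid
    for var in spec.components:
        if var not in fields:
            raise ValueError(f"no field supplied for selected variable {var!r}")
        f = fields[var]
        if f.grid != grid:
            raise ValueError(f"field {var!r} on a different grid")
        if f.missing.any():
            raise ValueError(f"field {var!r} has {f.n_missing} missing cells; gap-fill first")
    if cells is None:
        cells = np.arange(grid.n_cells)
    cells = np.asarray(cells, dtype=int)

    filters = daubechies_filters(spec.wavelet_order)
    jmax = max_decomposition_level(grid.n_cells, filters.L)
    if spec.J > jmax:
        raise ValueError(f"J={spec.J} exceeds max level {jmax} for {grid.n_cells} cells")

    columns: dict[str, np.ndarray] = {}
    order = _canonical_order(spec.J)
    for var, comps in spec.components.items():
        flat = fields[var].values.reshape(-1)
        comp_obj = None
        if spec.needs_decomposition(var):
            comp_obj = mra_components(flat, filters, spec.J, spec.extension_mode)
        for c in sorted(comps, key=order.index):
            if c == _RAW:
                columns[var] = flat[cells]
            else:
                columns[f"{var}_{c}"] = comp_obj.component(c)[cells]
    if spec.include_coordinates:
        rows_, cols_ = np.divmod(cells, grid.n_cols)
        columns["coord_x"] = grid.origin_x + (cols_ + 0.5) * grid.cell_size
        columns["coord_y"] = grid.origin_y + (rows_ + 0.5) * grid.cell_size
    return pd.DataFrame(columns, columns=spec.column_names())


def prune_by_importance(model, spec: FeatureSpec, epsilon: float = 0.005,
                        seed: int = 0) -> FeatureSpec:
    """Drop components whose normalized OOB permutation importance is below
    ``epsilon``; the best feature always survives.

    ``model`` is a :class:`~pmwave.ensemble.FittedForest` trained on exactly
    the columns of ``spec``.  Coordinates are dropped only if both fall
    below the threshold.
    """
    names = spec.column_names()
    if model.predictor_names != names:
        raise ValueError("model was not trained on the columns of this spec")
    imp = model.oob_permutation_importance(seed=seed)
    if epsilon <= 0:
        return spec
    keep = imp >= epsilon
    if not keep.any():
        raise ValueError(f"all {len(names)} features fall below epsilon={epsilon}")
    keep[imp.idxmax()] = True

    new_components: dict[str, tuple[str, ...]] = {}
    for var, comps in spec.components.items():
        kept = []
        for c in comps:
            col = var if c == _RAW else f"{var}_{c}"
            if keep[col]:
                kept.append(c)
        if kept:
            new_components[var] = tuple(kept)
    include_coords = spec.include_coordinates and bool(
        keep.get("coord_x", False) or keep.get("coord_y", False)
    )
    return replace(spec, components=new_components, include_coordinates=include_coords)
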