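"""The 1 km modeling grid and the moves that bring data onto it.

A :class:`GridSpec` is a planar, row-major raster: cell ``(i, j)`` spans
``[origin + j*cs, origin + (j+1)*cs)`` in x and similarly in y, with its
center at the half-offset.  Row 0 is the southernmost row (smallest y).
A :class:`Field` is one variable at one hour on such a grid, with an explicit
boolean missing mask so that satellite gaps are first-class.

Resampling operations:

* ``nearest_cell`` / ``assign_pixels_nearest`` -- point and pixel snapping,
  used for monitor records and for mapping coarse satellite AOD pixels to
  unique fine cells.
* ``regrid_bilinear`` -- tensor-product bilinear interpolation from a coarse
  raster (e.g. a 0.25 degree reanalysis) onto the fine grid.
* ``idw_downscale`` -- inverse-distance-weighted downscaling of coarse
  meteorology (e.g. 3 km forecast fields) to the fine grid.
* ``merge_observations`` -- collapse monitor records to one value per cell,
  with reference-grade monitors taking absolute precedence over low-cost
  sensors and same-source duplicates averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "GridSpec",
    "Field",
    "BilinearStencil",
    "nearest_cell",
    "hourly_average",
    "bilinear_interpolate",
    "regrid_bilinear",
    "idw_downscale",
    "assign_pixels_nearest",
    "merge_observations",
    "REF",
    "LC",
]

REF = "REF"  # reference-grade (regulatory) monitor
LC = "LC"  # low-cost sensor


@dataclass(frozen=True)
class GridSpec:
    """Planar modeling grid, row-major from the (origin_x, origin_y) corner."""

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        return self.origin_y + (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of (X, Y) centers, each shaped (n_rows, n_cols)."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def cell_index(self, row: int, col: int) -> int:
        return row * self.n_cols + col

    def __eq__(self, other) -> bool:
        if not isinstance(other, GridSpec):
            return NotImplemented
        return (
            np.isclose(self.origin_x, other.origin_x)
            and np.isclose(self.origin_y, other.origin_y)
            and np.isclose(self.cell_size, other.cell_size)
            and self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
        )

    def __hash__(self):
        return hash((round(self.origin_x, 9), round(self.origin_y, 9),
                     round(self.cell_size, 9), self.n_rows, self.n_cols))


@dataclass
class Field:
    """One variable, one hour, on a grid, with an explicit missing mask."""

    grid: GridSpec
    variable: str
    hour: object  # timestamp or integer hour index
    values: np.ndarray
    missing: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        shape = (self.grid.n_rows, self.grid.n_cols)
        if self.values.shape != shape:
            raise ValueError(f"values shape {self.values.shape} != grid shape {shape}")
        if self.missing.shape != shape:
            raise ValueError(f"missing shape {self.missing.shape} != grid shape {shape}")

    @classmethod
    def full(cls, grid: GridSpec, values, variable: str = "", hour=None) -> "Field":
        """A gap-free field from a dense value array."""
        values = np.asarray(values, dtype=float)
        return cls(grid=grid, variable=variable, hour=hour, values=values,
                   missing=np.isnan(values))

    def copy(self) -> "Field":
        return replace(self, values=self.values.copy(), missing=self.missing.copy())

    @property
    def n_missing(self) -> int:
        return int(self.missing.sum())

    def observed_values(self) -> np.ndarray:
        return self.values[~self.missing]


def nearest_cell(grid: GridSpec, point: tuple[float, float]) -> tuple[int, int]:
    """Cell (row, col) whose center is nearest to ``point``.

    Points up to half a cell outside the extent are clamped to the edge
    cell.  Exact ties between neighboring centers resolve to the
    lexicographically smaller (row, col).
    """
    x, y = point
    xmin, ymin, xmax, ymax = grid.extent
    half = 0.5 * grid.cell_size
    if not (xmin - half <= x <= xmax + half and ymin - half <= y <= ymax + half):
        raise ValueError(f"point ({x}, {y}) outside grid extent {grid.extent}")
    # center index minimizing |u - col|, ties to the smaller index
    u = (x - grid.origin_x) / grid.cell_size - 0.5
    v = (y - grid.origin_y) / grid.cell_size - 0.5
    col = int(np.clip(np.ceil(u - 0.5), 0, grid.n_cols - 1))
    row = int(np.clip(np.ceil(v - 0.5), 0, grid.n_rows - 1))
    return row, col


def hourly_average(times, values) -> float:
    """Mean of the non-missing samples within one clock hour.

    ``times`` are timestamps that must all fall in the same hour (this is a
    per-hour reducer, not a resampler); NaN samples are ignored and NaN is
    returned when nothing remains.
    """
    times = pd.DatetimeIndex(times)
    values = np.asarray(values, dtype=float)
    if len(times) != len(values):
        raise ValueError("times and values differ in length")
    if len(times) == 0:
        return float("nan")
    hours = times.floor("h")
    if hours.nunique() > 1:
        raise ValueError(f"samples span multiple hours: {sorted(hours.unique())}")
    good = ~np.isnan(values)
    if not good.any():
        return float("nan")
    return float(values[good].mean())


@dataclass(frozen=True)
class BilinearStencil:
    """A 2x2 corner stencil and a target point inside it.

    Corners follow the compass layout: S11 at (w1, v1), S21 at (w2, v1),
    S12 at (w1, v2), S22 at (w2, v2).
    """

    S11: float
    S12: float
    S21: float
    S22: float
    w1: float
    w2: float
    v1: float
    v2: float
    w: float
    v: float

    def __post_init__(self):
        if not (self.w1 < self.w2 and self.v1 < self.v2):
            raise ValueError(
                f"degenerate stencil rectangle: w ({self.w1}, {self.w2}), "
                f"v ({self.v1}, {self.v2})"
            )
        if not (self.w1 <= self.w <= self.w2 and self.v1 <= self.v <= self.v2):
            raise ValueError(f"target ({self.w}, {self.v}) outside stencil rectangle")


def bilinear_interpolate(stencil: BilinearStencil) -> float:
    """Tensor-product bilinear interpolation; exact on a + b*w + c*v + d*w*v."""
    s = stencil
    tw = (s.w - s.w1) / (s.w2 - s.w1)
    tv = (s.v - s.v1) / (s.v2 - s.v1)
    bottom = s.S11 * (1 - tw) + s.S21 * tw  # along w at v1
    top = s.S12 * (1 - tw) + s.S22 * tw  # along w at v2
    return float(bottom * (1 - tv) + top * tv)


def _stencil_indices(centers: np.ndarray, targets: np.ndarray):
    """Left index of the enclosing center interval, clamped at the edges."""
    i = np.searchsorted(centers, targets) - 1
    return np.clip(i, 0, len(centers) - 2)


def regrid_bilinear(coarse: Field, target: GridSpec) -> Field:
    """Bilinear interpolation of a coarse field onto every target cell center.

    Target centers outside the span of coarse centers are clamped onto the
    outermost coarse stencil (linear extrapolation at the rim).  Target cells
    whose stencil touches a missing coarse cell come out missing.
    """
    cg = coarse.grid
    if cg.n_rows < 2 or cg.n_cols < 2:
        raise ValueError("coarse grid needs at least 2x2 cells for bilinear regridding")
    txmin, tymin, txmax, tymax = target.extent
    cxmin, cymin, cxmax, cymax = cg.extent
    if txmax <= cxmin or txmin >= cxmax or tymax <= cymin or tymin >= cymax:
        raise ValueError("target grid does not overlap the coarse grid")

    xc, yc = cg.x_centers(), cg.y_centers()
    xt, yt = target.x_centers(), target.y_centers()
    jx = _stencil_indices(xc, xt)  # (n_cols_t,)
    iy = _stencil_indices(yc, yt)  # (n_rows_t,)
    tw = (xt - xc[jx]) / (xc[jx + 1] - xc[jx])
    tv = (yt - yc[iy]) / (yc[iy + 1] - yc[iy])

    V = coarse.values
    tw2 = tw[None, :]
    tv2 = tv[:, None]
    IY, JX = iy[:, None], jx[None, :]
    vals = (
        V[IY, JX] * (1 - tw2) * (1 - tv2)
        + V[IY, JX + 1] * tw2 * (1 - tv2)
        + V[IY + 1, JX] * (1 - tw2) * tv2
        + V[IY + 1, JX + 1] * tw2 * tv2
    )
    M = coarse.missing
    miss = M[IY, JX] | M[IY, JX + 1] | M[IY + 1, JX] | M[IY + 1, JX + 1]
    vals = np.where(miss, np.nan, vals)
    return Field(grid=target, variable=coarse.variable, hour=coarse.hour,
                 values=vals, missing=miss)


def idw_downscale(coarse: Field, target: GridSpec, power: float = 2.0, k: int = 4) -> Field:
    """Inverse-distance-weighted downscaling onto every target cell center.

    Each target value is ``sum(w_i z_i) / sum(w_i)`` over the ``k`` nearest
    non-missing coarse centers with ``w_i = d_i**(-power)``; a target center
    coinciding with a source center returns that source value exactly.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if power <= 0:
        raise ValueError(f"power must be positive, got {power}")
    cg = coarse.grid
    obs = ~coarse.missing
    n_src = int(obs.sum())
    if n_src == 0:
        raise ValueError("no non-missing source cells for IDW")
    if n_src < k:
        raise ValueError(f"only {n_src} non-missing source cells, need k={k}")
    CX, CY = cg.cell_centers()
    src_xy = np.column_stack([CX[obs], CY[obs]])
    src_z = coarse.values[obs]
    TX, TY = target.cell_centers()
    tgt_xy = np.column_stack([TX.ravel(), TY.ravel()])
    dist, idx = cKDTree(src_xy).query(tgt_xy, k=k)
    dist = np.atleast_2d(dist.reshape(len(tgt_xy), -1))
    idx = np.atleast_2d(idx.reshape(len(tgt_xy), -1))
    exact = dist[:, 0] == 0.0
    with np.errstate(divide="ignore"):
        w = dist ** (-power)
    w[~np.isfinite(w)] = 0.0
    num = (w * src_z[idx]).sum(axis=1)
    den = w.sum(axis=1)
    out = np.empty(len(tgt_xy))
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    out[exact] = src_z[idx[exact, 0]]
    vals = out.reshape(target.n_rows, target.n_cols)
    return Field(grid=target, variable=coarse.variable, hour=coarse.hour,
                 values=vals, missing=np.zeros_like(vals, dtype=bool))


def assign_pixels_nearest(
    pixel_xy: np.ndarray, pixel_values: np.ndarray, target: GridSpec, hour=None,
    variable: str = "",
) -> Field:
    """Snap coarse satellite pixels to unique nearest target cells.

    Each pixel lands in the single cell nearest its center; when several
    pixels land in one cell their values are averaged.  Cells that receive
    no pixel stay missing -- they are exactly the cells later handled by
    gap-filling.  Pixels outside the (half-cell padded) extent are dropped.
    """
    pixel_xy = np.asarray(pixel_xy, dtype=float)
    pixel_values = np.asarray(pixel_values, dtype=float)
    vals = np.zeros((target.n_rows, target.n_cols))
    counts = np.zeros((target.n_rows, target.n_cols))
    for (x, y), z in zip(pixel_xy, pixel_values):
        if np.isnan(z):
            continue
        try:
            r, c = nearest_cell(target, (x, y))
        except ValueError:
            continue
        vals[r, c] += z
        counts[r, c] += 1
    miss = counts == 0
    with np.errstate(invalid="ignore"):
        vals = np.where(miss, np.nan, vals / np.maximum(counts, 1))
    return Field(grid=target, variable=variable, hour=hour, values=vals, missing=miss)


def merge_observations(records: pd.DataFrame, grid: GridSpec, hour=None) -> pd.DataFrame:
    """Collapse monitor records to one PM2.5 value per occupied cell.

    ``records`` needs columns ``x, y, pm25, source`` (source in {REF, LC})
    and optionally ``site_id`` and ``hour``.  Reference-grade precedence is
    absolute: wherever any REF record falls in a cell, all LC records in that
    cell are discarded; duplicates within the surviving source are averaged.

    Returns a frame with one row per occupied cell: ``row, col, cell, pm25,
    source, n_records, site_ids``.
    """
    required = {"x", "y", "pm25", "source"}
    missing_cols = required - set(records.columns)
    if missing_cols:
        raise ValueError(f"records missing columns {sorted(missing_cols)}")
    bad = ~records["source"].isin([REF, LC])
    if bad.any():
        raise ValueError(f"unknown source tags: {records.loc[bad, 'source'].unique()}")
    if hour is not None and "hour" in records.columns:
        records = records[records["hour"] == hour]
    if records.empty:
        return pd.DataFrame(columns=["row", "col", "cell", "pm25", "source",
                                     "n_records", "site_ids"])
    rows, cols = [], []
    for rid, rec in records.iterrows():
        try:
            r, c = nearest_cell(grid, (rec["x"], rec["y"]))
        except ValueError as err:
            raise ValueError(f"record {rid} outside grid: {err}") from err
        rows.append(r)
        cols.append(c)
    df = records.copy()
    df["row"], df["col"] = rows, cols
    df["cell"] = df["row"] * grid.n_cols + df["col"]

    out = []
    for cell, group in df.groupby("cell"):
        ref = group[group["source"] == REF]
        chosen = ref if len(ref) else group
        tag = REF if len(ref) else LC
        out.append({
            "row": int(chosen["row"].iloc[0]),
            "col": int(chosen["col"].iloc[0]),
            "cell": int(cell),
            "pm25": float(chosen["pm25"].mean()),
            "source": tag,
            "n_records": int(len(chosen)),
            "site_ids": list(chosen["site_id"]) if "site_id" in chosen.columns else [],
        })
    return pd.DataFrame(out).sort_values("cell").reset_index(drop=True)
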