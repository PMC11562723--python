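"""Grid construction, resampling and observation merging."""

import numpy as np
import pandas as pd
import pytest

from pmwave.grid import (
    LC,
    REF,
    BilinearStencil,
    Field,
    GridSpec,
    assign_pixels_nearest,
    bilinear_interpolate,
    hourly_average,
    idw_downscale,
    merge_observations,
    nearest_cell,
    regrid_bilinear,
)


def grid(rows=10, cols=10, cs=1.0, ox=0.0, oy=0.0):
    return GridSpec(origin_x=ox, origin_y=oy, cell_size=cs, n_rows=rows, n_cols=cols)


class TestNearestCell:
    def test_cell_center_maps_to_itself(self):
        g = grid()
        x = g.origin_x + (7 + 0.5) * g.cell_size
        y = g.origin_y + (3 + 0.5) * g.cell_size
        assert nearest_cell(g, (x, y)) == (3, 7)

    def test_tie_resolves_to_lexicographically_smaller(self):
        g = grid()
        # point on the shared edge of columns 4 and 5, and of rows 2 and 3
        assert nearest_cell(g, (5.0, 2.5)) == (2, 4)
        assert nearest_cell(g, (4.5, 3.0)) == (2, 4)

    def test_agrees_with_brute_force(self, rng):
        g = grid(rows=13, cols=17, cs=0.7, ox=-3.0, oy=5.0)
        X, Y = g.cell_centers()
        centers = np.column_stack([X.ravel(), Y.ravel()])
        xmin, ymin, xmax, ymax = g.extent
        pts = np.column_stack([
            rng.uniform(xmin, xmax, size=1000),
            rng.uniform(ymin, ymax, size=1000),
        ])
        for x, y in pts:
            d2 = (centers[:, 0] - x) ** 2 + (centers[:, 1] - y) ** 2
            flat = int(np.argmin(d2))  # argmin takes the first = lexicographic min
            expected = (flat // g.n_cols, flat % g.n_cols)
            assert nearest_cell(g, (x, y)) == expected

    def test_outside_extent_rejected_with_coordinates(self):
        g = grid()
        with pytest.raises(ValueError, match=r"\(50.*\).*outside"):
            nearest_cell(g, (50.0, 5.0))

    def test_half_cell_tolerance_clamps_to_edge(self):
        g = grid()
        assert nearest_cell(g, (-0.4, 0.2)) == (0, 0)


class TestHourlyAverage:
    def test_twelve_five_minute_values(self):
        times = pd.date_range("2020-08-22 14:00", periods=12, freq="5min")
        assert hourly_average(times, np.arange(12.0)) == pytest.approx(5.5)

    def test_mean_of_available_only(self):
        times = pd.to_datetime(["2020-08-22 14:05", "2020-08-22 14:20",
                                "2020-08-22 14:40"])
        assert hourly_average(times, [0.2, np.nan, 0.4]) == pytest.approx(0.3)

    def test_all_missing_gives_missing(self):
        times = pd.to_datetime(["2020-08-22 14:05", "2020-08-22 14:20"])
        assert np.isnan(hourly_average(times, [np.nan, np.nan]))

    def test_mixed_hours_rejected(self):
        times = pd.to_datetime(["2020-08-22 14:55", "2020-08-22 15:05"])
        with pytest.raises(ValueError, match="multiple hours"):
            hourly_average(times, [1.0, 2.0])


class TestBilinear:
    def unit_square(self, S11, S21, S12, S22, w, v):
        return BilinearStencil(S11=S11, S12=S12, S21=S21, S22=S22,
                               w1=0.0, w2=1.0, v1=0.0, v2=1.0, w=w, v=v)

    def test_constant_corners(self):
        s = self.unit_square(4.2, 4.2, 4.2, 4.2, 0.3, 0.8)
        assert bilinear_interpolate(s) == pytest.approx(4.2)

    def test_corner_recovery(self):
        s = self.unit_square(1.0, 2.0, 3.0, 4.0, 0.0, 0.0)
        assert bilinear_interpolate(s) == pytest.approx(1.0)

    def test_affine_field_worked_example(self):
        # f = w + 2v: S11=0, S21=1, S12=2, S22=3, target (0.25, 0.5) -> 1.25
        s = self.unit_square(0.0, 1.0, 2.0, 3.0, 0.25, 0.5)
        assert bilinear_interpolate(s) == pytest.approx(1.25)

    def test_degenerate_rectangle_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            BilinearStencil(S11=0, S12=0, S21=0, S22=0,
                            w1=1.0, w2=1.0, v1=0.0, v2=1.0, w=1.0, v=0.5)


class TestRegridBilinear:
    def coarse_field(self, values, cs=5.0):
        values = np.asarray(values, dtype=float)
        g = grid(rows=values.shape[0], cols=values.shape[1], cs=cs)
        return Field(grid=g, variable="v", hour=0, values=values,
                     missing=np.zeros(values.shape, bool))

    def test_constant_is_preserved(self):
        coarse = self.coarse_field(np.full((4, 4), 3.7))
        fine = regrid_bilinear(coarse, grid(rows=20, cols=20, cs=1.0))
        assert np.allclose(fine.values, 3.7)

    def test_planar_field_reproduced_exactly(self):
        g = grid(rows=6, cols=5, cs=4.0)
        X, Y = g.cell_centers()
        coarse = self.coarse_field(2.0 + 0.3 * X + 0.7 * Y, cs=4.0)
        tgt = grid(rows=24, cols=20, cs=1.0)
        fine = regrid_bilinear(coarse, tgt)
        TX, TY = tgt.cell_centers()
        assert np.abs(fine.values - (2.0 + 0.3 * TX + 0.7 * TY)).max() < 1e-12

    def test_matches_per_cell_stencil_oracle(self, rng):
        coarse = self.coarse_field(rng.normal(size=(5, 6)), cs=3.0)
        tgt = grid(rows=9, cols=11, cs=1.3, ox=1.0, oy=1.0)
        fine = regrid_bilinear(coarse, tgt)
        xc, yc = coarse.grid.x_centers(), coarse.grid.y_centers()
        for i in range(tgt.n_rows):
            for j in range(tgt.n_cols):
                x = tgt.origin_x + (j + 0.5) * tgt.cell_size
                y = tgt.origin_y + (i + 0.5) * tgt.cell_size
                jx = int(np.clip(np.searchsorted(xc, x) - 1, 0, len(xc) - 2))
                iy = int(np.clip(np.searchsorted(yc, y) - 1, 0, len(yc) - 2))
                s = BilinearStencil(
                    S11=coarse.values[iy, jx], S21=coarse.values[iy, jx + 1],
                    S12=coarse.values[iy + 1, jx], S22=coarse.values[iy + 1, jx + 1],
                    w1=xc[jx], w2=xc[jx + 1], v1=yc[iy], v2=yc[iy + 1], w=x, v=y)
                assert fine.values[i, j] == pytest.approx(bilinear_interpolate(s), abs=1e-12)

    def test_never_invents_extrema_inside_center_hull(self, rng):
        # true interpolation is a convex combination; only the rim cells
        # outside the coarse-center hull extrapolate (by design)
        coarse = self.coarse_field(rng.normal(size=(6, 6)), cs=2.0)
        tgt = grid(rows=12, cols=12, cs=1.0)
        fine = regrid_bilinear(coarse, tgt)
        xc, yc = coarse.grid.x_centers(), coarse.grid.y_centers()
        TX, TY = tgt.cell_centers()
        interior = ((TX >= xc[0]) & (TX <= xc[-1]) & (TY >= yc[0]) & (TY <= yc[-1]))
        assert fine.values[interior].min() >= coarse.values.min() - 1e-12
        assert fine.values[interior].max() <= coarse.values.max() + 1e-12

    def test_disjoint_grids_rejected(self):
        coarse = self.coarse_field(np.ones((4, 4)), cs=1.0)
        with pytest.raises(ValueError, match="overlap"):
            regrid_bilinear(coarse, grid(rows=4, cols=4, cs=1.0, ox=100.0, oy=100.0))


class TestIdwDownscale:
    def test_coincident_center_returns_source_value(self):
        g = grid(rows=4, cols=4, cs=2.0)
        vals = np.full((4, 4), 1.0)
        vals[1, 1] = 7.0
        coarse = Field(grid=g, variable="v", hour=0, values=vals,
                       missing=np.zeros((4, 4), bool))
        # same geometry: every target center coincides with a source center
        out = idw_downscale(coarse, g, power=2.0, k=4)
        assert out.values[1, 1] == pytest.approx(7.0)
        assert np.allclose(out.values, vals)

    def test_two_equidistant_sources_average(self):
        g = grid(rows=1, cols=2, cs=2.0)
        coarse = Field(grid=g, variable="v", hour=0, values=np.array([[2.0, 4.0]]),
                       missing=np.zeros((1, 2), bool))
        tgt = GridSpec(origin_x=1.0, origin_y=0.0, cell_size=2.0, n_rows=1, n_cols=1)
        out = idw_downscale(coarse, tgt, power=2.0, k=2)
        assert out.values[0, 0] == pytest.approx(3.0)

    def test_matches_brute_force_weighted_sum(self, rng):
        g = grid(rows=7, cols=8, cs=3.0)
        vals = rng.normal(size=(7, 8))
        miss = rng.random((7, 8)) < 0.2
        vals[miss] = np.nan
        coarse = Field(grid=g, variable="v", hour=0, values=vals, missing=miss)
        tgt = grid(rows=10, cols=10, cs=1.7, ox=0.4, oy=0.9)
        k, power = 5, 1.5
        out = idw_downscale(coarse, tgt, power=power, k=k)
        X, Y = g.cell_centers()
        sx, sy, sz = X[~miss], Y[~miss], vals[~miss]
        for i in range(tgt.n_rows):
            for j in range(tgt.n_cols):
                x = tgt.origin_x + (j + 0.5) * tgt.cell_size
                y = tgt.origin_y + (i + 0.5) * tgt.cell_size
                d = np.hypot(sx - x, sy - y)
                order = np.argsort(d)
                if np.isclose(d[order[k - 1]], d[order[k]]):
                    continue  # tied k-th neighbor: either resolution is valid
                near = order[:k]
                if d[near[0]] == 0:
                    expected = sz[near[0]]
                else:
                    w = d[near] ** (-power)
                    expected = np.sum(w * sz[near]) / np.sum(w)
                assert out.values[i, j] == pytest.approx(expected, rel=1e-10)

    def test_convex_combination_bounds(self, rng):
        g = grid(rows=6, cols=6, cs=2.0)
        coarse = Field(grid=g, variable="v", hour=0, values=rng.normal(size=(6, 6)),
                       missing=np.zeros((6, 6), bool))
        out = idw_downscale(coarse, grid(rows=12, cols=12, cs=1.0), power=2.0, k=4)
        assert out.values.min() >= coarse.values.min() - 1e-12
        assert out.values.max() <= coarse.values.max() + 1e-12

    def test_too_few_sources_rejected(self):
        g = grid(rows=2, cols=2, cs=1.0)
        vals = np.array([[1.0, np.nan], [np.nan, np.nan]])
        coarse = Field(grid=g, variable="v", hour=0, values=vals, missing=np.isnan(vals))
        with pytest.raises(ValueError, match="non-missing"):
            idw_downscale(coarse, g, k=4)


class TestAssignPixelsNearest:
    def test_each_pixel_lands_in_unique_nearest_cell(self):
        g = grid(rows=4, cols=4, cs=1.0)
        xy = np.array([[0.5, 0.5], [3.4, 2.6], [0.6, 0.4]])
        out = assign_pixels_nearest(xy, np.array([1.0, 2.0, 3.0]), g)
        assert out.values[0, 0] == pytest.approx(2.0)  # two pixels averaged
        assert out.values[2, 3] == pytest.approx(2.0)
        assert out.n_missing == g.n_cells - 2


class TestMergeObservations:
    def records(self, rows):
        return pd.DataFrame(rows, columns=["site_id", "source", "x", "y", "pm25"])

    def test_reference_overrides_lowcost(self):
        recs = self.records([("a", REF, 0.5, 0.5, 10.0), ("b", LC, 0.6, 0.4, 20.0)])
        out = merge_observations(recs, grid())
        assert len(out) == 1
        assert out.loc[0, "pm25"] == pytest.approx(10.0)
        assert out.loc[0, "source"] == REF

    def test_lowcost_duplicates_average(self):
        recs = self.records([("a", LC, 0.5, 0.5, 8.0), ("b", LC, 0.6, 0.4, 12.0)])
        out = merge_observations(recs, grid())
        assert out.loc[0, "pm25"] == pytest.approx(10.0)
        assert out.loc[0, "source"] == LC

    def test_reference_duplicates_average(self):
        recs = self.records([("a", REF, 0.5, 0.5, 10.0), ("b", REF, 0.6, 0.4, 14.0)])
        out = merge_observations(recs, grid())
        assert out.loc[0, "pm25"] == pytest.approx(12.0)

    def test_one_row_per_occupied_cell(self):
        recs = self.records([
            ("a", REF, 0.5, 0.5, 10.0), ("b", LC, 0.5, 0.5, 99.0),
            ("c", LC, 5.5, 5.5, 20.0), ("d", LC, 8.5, 2.5, 30.0),
        ])
        out = merge_observations(recs, grid())
        assert len(out) == 3
        assert set(out["source"]) == {REF, LC}

    def test_record_outside_grid_rejected_with_id(self):
        recs = self.records([("far-away", LC, 99.0, 99.0, 5.0)])
        with pytest.raises(ValueError, match="outside grid"):
            merge_observations(recs, grid())

    def test_unknown_source_rejected(self):
        recs = self.records([("a", "XX", 0.5, 0.5, 5.0)])
        with pytest.raises(ValueError, match="unknown source"):
            merge_observations(recs, grid())
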