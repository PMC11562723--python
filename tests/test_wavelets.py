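"""Daubechies filters, pyramid DWT, and additive multiresolution components.

The single-level oracle used here is written as plain index arithmetic
(scalar loops over extended signals), independent of the vectorized
implementation; PyWavelets serves as a second, external cross-check.
"""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings, strategies as st

from pmwave.grid import Field, GridSpec
from pmwave.wavelets import (
    daubechies_filters,
    dwt_decompose,
    field_to_signal,
    max_decomposition_level,
    mra_components,
    reconstruct,
    signal_to_field,
)

MODE_MAP = {"symmetric": "symmetric", "periodic": "periodization"}


# -- independent single-level oracle ----------------------------------------

def oracle_extend(x, m, mode):
    n = len(x)
    out = np.empty(n + 2 * m)
    for i in range(-m, n + m):
        if mode == "symmetric":
            j = i % (2 * n)
            out[i + m] = x[j] if j < n else x[2 * n - 1 - j]
        else:
            out[i + m] = x[i % n]
    return out


def oracle_dwt_single(x, filters, mode):
    """Extend, correlate with the analysis filters, keep every second sample."""
    L = filters.L
    if mode == "periodic" and len(x) % 2 == 1:
        x = np.append(x, x[-1])
    n = len(x)
    ext = oracle_extend(x, L - 1, mode)
    out_len = (n + L - 1) // 2 if mode == "symmetric" else n // 2
    start = 1 if mode == "symmetric" else L // 2
    cA = np.empty(out_len)
    cD = np.empty(out_len)
    for i in range(out_len):
        sa = sd = 0.0
        for k in range(L):  # correlation with the filter as declared
            sa += filters.lowpass[k] * ext[start + 2 * i + k]
            sd += filters.highpass[k] * ext[start + 2 * i + k]
        cA[i] = sa
        cD[i] = sd
    return cA, cD


def oracle_decompose(x, filters, J, mode):
    details = []
    approx = np.asarray(x, float)
    for _ in range(J):
        approx, d = oracle_dwt_single(approx, filters, mode)
        details.append(d)
    return approx, details


# -- filters -----------------------------------------------------------------

class TestDaubechiesFilters:
    def test_order_one_is_haar(self):
        f = daubechies_filters(1)
        assert np.allclose(f.lowpass, [1 / np.sqrt(2), 1 / np.sqrt(2)])
        assert f.family == "haar"

    @pytest.mark.parametrize("p", [1, 2, 3, 4, 5, 7, 10])
    def test_filter_pair_invariants(self, p):
        f = daubechies_filters(p)
        assert f.L == 2 * p
        assert np.sum(f.lowpass) == pytest.approx(np.sqrt(2), abs=1e-10)
        assert np.sum(f.lowpass**2) == pytest.approx(1.0, abs=1e-10)
        # quadrature mirror
        qmf = [(-1.0) ** k * f.lowpass[f.L - 1 - k] for k in range(f.L)]
        assert np.allclose(f.highpass, qmf, atol=1e-14)
        # p vanishing moments of the highpass; at high p the moment sum
        # cancels terms of magnitude ~k**m, so the attainable bound is the
        # double-precision cancellation floor, not a fixed 1e-8
        k = np.arange(f.L)
        for m in range(p):
            floor_ = 1e-13 * np.sum(np.abs(k**m * f.highpass))
            assert abs(np.sum(k**m * f.highpass)) < max(1e-8, floor_)

    @pytest.mark.parametrize("p", [2, 5, 8])
    def test_even_lag_orthogonality(self, p):
        f = daubechies_filters(p)
        for lag in range(2, f.L, 2):
            assert abs(np.sum(f.lowpass[lag:] * f.highpass[:-lag])) < 1e-10
            assert abs(np.sum(f.lowpass[:-lag] * f.highpass[lag:])) < 1e-10
            assert abs(np.sum(f.lowpass[lag:] * f.lowpass[:-lag])) < 1e-10

    @pytest.mark.parametrize("p", [0, 11, -3])
    def test_unsupported_order_rejected(self, p):
        with pytest.raises(ValueError, match="order"):
            daubechies_filters(p)

    @pytest.mark.parametrize("p", [2, 5, 10])
    def test_matches_reference_library(self, p):
        f = daubechies_filters(p)
        ref = pywt.Wavelet(f"db{p}")
        assert np.allclose(f.lowpass, ref.rec_lo, atol=1e-12)
        assert np.allclose(f.highpass, ref.rec_hi, atol=1e-12)


class TestMaxDecompositionLevel:
    def test_full_state_grid_supports_fifteen_levels(self):
        # 493,561 cells with a length-10 filter
        assert max_decomposition_level(493561, 10) == 15

    def test_power_of_two_with_haar(self):
        assert max_decomposition_level(8, 2) == 3

    def test_hundred_samples_with_db5(self):
        assert max_decomposition_level(100, 10) == 3  # floor(log2(100/9))

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            max_decomposition_level(8, 10)


# -- decomposition ------------------------------------------------------------

class TestDwtDecompose:
    def test_constant_signal_has_zero_details(self):
        f = daubechies_filters(1)
        pyr = dwt_decompose(np.full(32, 3.3), f, 1, "symmetric")
        assert np.allclose(pyr.details[0], 0.0, atol=1e-12)

    def test_haar_periodic_worked_example(self):
        # (1,2,3,4) -> approximation (3, 7)/sqrt(2); details -(1, 1)/sqrt(2)
        f = daubechies_filters(1)
        pyr = dwt_decompose(np.array([1.0, 2, 3, 4]), f, 1, "periodic")
        assert np.allclose(pyr.approx, np.array([3.0, 7.0]) / np.sqrt(2))
        assert np.allclose(pyr.details[0], np.array([-1.0, -1.0]) / np.sqrt(2))

    @pytest.mark.parametrize("mode", ["symmetric", "periodic"])
    @pytest.mark.parametrize("p,n,J", [(1, 37, 3), (2, 64, 3), (5, 64, 2), (5, 300, 4)])
    def test_pyramid_equals_naive_oracle(self, mode, p, n, J, rng):
        f = daubechies_filters(p)
        x = rng.normal(size=n)
        pyr = dwt_decompose(x, f, J, mode)
        oa, od = oracle_decompose(x, f, J, mode)
        assert np.allclose(pyr.approx, oa, atol=1e-10)
        for j in range(J):
            assert np.allclose(pyr.details[j], od[j], atol=1e-10)

    @pytest.mark.parametrize("mode", ["symmetric", "periodic"])
    @pytest.mark.parametrize("p,n,J", [(1, 48, 3), (3, 100, 3), (5, 257, 3)])
    def test_coefficients_match_reference_library(self, mode, p, n, J, rng):
        name = "haar" if p == 1 else f"db{p}"
        f = daubechies_filters(p)
        x = rng.normal(size=n)
        pyr = dwt_decompose(x, f, J, mode)
        ref = pywt.wavedec(x, name, mode=MODE_MAP[mode], level=J)
        assert np.allclose(pyr.approx, ref[0], atol=1e-10)
        for j in range(1, J + 1):
            assert np.allclose(pyr.details[j - 1], ref[-j], atol=1e-10)

    def test_excessive_level_rejected(self):
        f = daubechies_filters(5)
        with pytest.raises(ValueError, match="level"):
            dwt_decompose(np.zeros(100), f, 4, "symmetric")

    def test_missing_values_rejected(self):
        f = daubechies_filters(2)
        x = np.ones(64)
        x[10] = np.nan
        with pytest.raises(ValueError, match="missing"):
            dwt_decompose(x, f, 2, "symmetric")

    def test_parseval_under_periodic_extension(self, rng):
        f = daubechies_filters(5)
        x = rng.normal(size=256)
        pyr = dwt_decompose(x, f, 4, "periodic")
        coeff_energy = sum(float(np.sum(c**2)) for c in [pyr.approx] + pyr.details)
        assert coeff_energy == pytest.approx(float(np.sum(x**2)), rel=1e-8)


# -- multiresolution components ----------------------------------------------

class TestMraComponents:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        n=st.integers(64, 1024),
        p=st.integers(1, 5),
        mode=st.sampled_from(["symmetric", "periodic"]),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_components_sum_to_signal(self, n, p, mode, seed):
        f = daubechies_filters(p)
        J = min(5, max_decomposition_level(n, f.L))
        x = np.random.default_rng(seed).normal(size=n)
        comp = mra_components(x, f, J, mode)
        err = np.abs(comp.reconstruct() - x).max() / np.abs(x).max()
        assert err <= 1e-8
        assert len(comp.details) == J
        assert all(len(d) == n for d in comp.details)
        assert len(comp.approximation) == n

    def test_db5_annihilates_cubics_away_from_boundaries(self):
        t = np.linspace(-1, 1, 256)
        x = 0.3 + 1.5 * t - 2.0 * t**2 + 0.8 * t**3
        f = daubechies_filters(5)
        comp = mra_components(x, f, 3, "symmetric")
        margin = f.L * 2**3  # boundary-affected run at the deepest level
        interior = slice(margin, len(x) - margin)
        bound = 1e-6 * np.abs(x).max()
        for d in comp.details:
            assert np.abs(d[interior]).max() < bound

    def test_haar_splits_alternating_signal(self):
        x = np.tile([1.0, -1.0], 32)
        comp = mra_components(x, daubechies_filters(1), 1, "periodic")
        assert np.abs(comp.approximation).max() < 1e-12
        assert np.allclose(comp.details[0], x, atol=1e-12)

    @pytest.mark.parametrize("mode", ["symmetric", "periodic"])
    def test_bands_match_reference_library_mra(self, mode, rng):
        x = rng.normal(size=300)
        f = daubechies_filters(5)
        comp = mra_components(x, f, 3, mode)
        ref = pywt.mra(x, "db5", level=3, transform="dwt", mode=MODE_MAP[mode])
        assert np.allclose(comp.approximation, ref[0], atol=1e-6)
        for j in range(1, 4):
            assert np.allclose(comp.details[j - 1], ref[-j], atol=1e-6)

    def test_component_lookup_by_name(self, rng):
        x = rng.normal(size=128)
        comp = mra_components(x, daubechies_filters(2), 3, "symmetric")
        assert np.array_equal(comp.component("l_3"), comp.approximation)
        assert np.array_equal(comp.component("h_2"), comp.details[1])
        with pytest.raises(KeyError):
            comp.component("l_2")

    def test_full_reconstruction_from_pyramid(self, rng):
        x = rng.normal(size=200)
        f = daubechies_filters(4)
        pyr = dwt_decompose(x, f, 3, "symmetric")
        assert np.allclose(reconstruct(pyr), x, atol=1e-10)


# -- field flattening ---------------------------------------------------------

class TestFieldSignal:
    def test_row_major_flattening(self):
        g = GridSpec(origin_x=0, origin_y=0, cell_size=1.0, n_rows=2, n_cols=3)
        vals = np.array([[1.0, 2, 3], [4, 5, 6]])
        fld = Field(grid=g, variable="v", hour=0, values=vals,
                    missing=np.zeros((2, 3), bool))
        assert np.array_equal(field_to_signal(fld), [1, 2, 3, 4, 5, 6])

    def test_round_trip_identity(self, rng):
        g = GridSpec(origin_x=0, origin_y=0, cell_size=1.0, n_rows=8, n_cols=9)
        vals = rng.normal(size=(8, 9))
        fld = Field(grid=g, variable="v", hour=0, values=vals,
                    missing=np.zeros((8, 9), bool))
        back = signal_to_field(field_to_signal(fld), g)
        assert np.array_equal(back.values, vals)

    def test_missing_cells_rejected(self):
        g = GridSpec(origin_x=0, origin_y=0, cell_size=1.0, n_rows=2, n_cols=3)
        vals = np.ones((2, 3))
        miss = np.zeros((2, 3), bool)
        miss[0, 1] = True
        fld = Field(grid=g, variable="v", hour=0, values=vals, missing=miss)
        with pytest.raises(ValueError, match="missing"):
            field_to_signal(fld)

    def test_state_grid_cell_count_supports_level_fifteen(self):
        # row-major flattening of the full modeling grid yields a signal whose
        # db5 maximum decomposition level is 15
        f = daubechies_filters(5)
        assert max_decomposition_level(493561, f.L) == 15
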