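"""Orthogonal Daubechies wavelet machinery for spatial-field signals.

Implements the discrete wavelet transform (DWT) as the classic pyramid of
filter-and-downsample steps, and the additive multiresolution analysis (MRA)

    S = l_J + h_1 + ... + h_J

in which the approximation ``l_J`` carries the smooth, low-frequency trend of
a signal and each detail ``h_j`` carries the fluctuations at dyadic scale
``2**j``.  Gridded fields are flattened row-major to one-dimensional signals
before decomposition, so "low frequency" means smooth variation along the
row-major scan of the grid.

Filter-sign convention
----------------------
``lowpass`` is the minimum-phase Daubechies sequence (the orientation whose
first entry is ``0.4829...`` for order 2) and the highpass is its quadrature
mirror ``g[k] = (-1)**k * lowpass[L-1-k]``.  Decomposition correlates with
these filters (i.e. convolves with their reversals); all worked values in the
test-suite are stated under this convention.

Boundary handling
-----------------
Two extension modes are provided.  ``"symmetric"`` (default) extends by
half-point reflection and keeps ``floor((n+L-1)/2)`` coefficients per band --
the common toolbox default, mildly redundant but artifact-free at the edges.
``"periodic"`` wraps the (even-length-padded) signal and keeps ``ceil(n/2)``
coefficients, which makes the transform orthonormal, so the coefficient
energy equals the signal energy exactly.  Perfect reconstruction holds for
both modes, hence the additive MRA identity holds by linearity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, floor, log2

import numpy as np

from .grid import Field, GridSpec

__all__ = [
    "WaveletFilterPair",
    "CoefficientPyramid",
    "MRAComponents",
    "daubechies_filters",
    "max_decomposition_level",
    "dwt_decompose",
    "reconstruct",
    "mra_components",
    "field_to_signal",
    "signal_to_field",
]

_MODES = ("symmetric", "periodic")


@dataclass(frozen=True)
class WaveletFilterPair:
    """Orthonormal lowpass/highpass analysis pair of length ``L = 2p``."""

    family: str
    lowpass: np.ndarray
    highpass: np.ndarray

    @property
    def L(self) -> int:
        return len(self.lowpass)

    @property
    def vanishing_moments(self) -> int:
        return self.L // 2


def daubechies_filters(p: int) -> WaveletFilterPair:
    """Build the order-``p`` Daubechies filter pair by spectral factorization.

    The lowpass transfer function is ``m0(z) = ((1+z)/2)**p * Q(z)`` where
    ``|Q|**2`` on the unit circle equals the Bezout polynomial
    ``P(y) = sum_k C(p-1+k, k) y**k`` evaluated at ``y = sin**2(w/2)``.
    Roots of ``P`` are mapped to reciprocal pairs in ``z`` and the root
    inside the unit circle is kept from each pair (minimum phase).  ``p = 1``
    reduces to the Haar pair ``(1/sqrt(2), 1/sqrt(2))``.

    Parameters
    ----------
    p : int
        Number of vanishing moments, 1..10.
    """
    if not 1 <= int(p) <= 10:
        raise ValueError(f"Daubechies order must be in 1..10, got {p}")
    p = int(p)
    if p == 1:
        q = np.array([1.0])
    else:
        bezout = [comb(p - 1 + k, k) for k in range(p)]  # ascending in y
        yroots = np.roots(bezout[::-1])
        zroots = []
        for y in yroots:
            b = 2.0 - 4.0 * y
            disc = np.sqrt(b * b - 4.0 + 0j)
            z1, z2 = (b + disc) / 2.0, (b - disc) / 2.0
            zroots.append(z1 if abs(z1) < 1.0 else z2)
        q = np.real(np.poly(zroots))
    lowpass = np.array([1.0])
    for _ in range(p):
        lowpass = np.convolve(lowpass, [1.0, 1.0])
    lowpass = np.convolve(lowpass, q)
    lowpass = lowpass * np.sqrt(2.0) / lowpass.sum()
    L = len(lowpass)
    highpass = np.array([(-1.0) ** k * lowpass[L - 1 - k] for k in range(L)])
    family = "haar" if p == 1 else f"db{p}"
    return WaveletFilterPair(family=family, lowpass=lowpass, highpass=highpass)


def max_decomposition_level(n: int, L: int) -> int:
    """Largest scale ``J = floor(log2(n / (L - 1)))`` supportable by ``n``.

    This is the deepest level at which each band still holds at least one
    coefficient driven by the data rather than purely by boundary extension.
    """
    n, L = int(n), int(L)
    if L < 2:
        raise ValueError(f"filter length must be >= 2, got {L}")
    if n < L:
        raise ValueError(f"signal length {n} shorter than filter length {L}")
    return floor(log2(n / (L - 1)))


# -- single-level transforms -------------------------------------------------

def _extend(x: np.ndarray, m: int, mode: str) -> np.ndarray:
    """Pad ``x`` by ``m`` samples on each side under the extension rule."""
    n = len(x)
    if mode == "symmetric":
        # half-point reflection is periodic with period 2n: [x, x[::-1]]
        pattern = np.concatenate([x, x[::-1]])
        idx = np.arange(-m, n + m) % (2 * n)
        return pattern[idx]
    if mode == "periodic":
        idx = np.arange(-m, n + m) % n
        return x[idx]
    raise ValueError(f"unknown extension mode {mode!r}; choose from {_MODES}")


def _dwt_single(x: np.ndarray, filters: WaveletFilterPair, mode: str):
    """One analysis step: extend, correlate, downsample by 2."""
    L = filters.L
    dec_lo = filters.lowpass[::-1]
    dec_hi = filters.highpass[::-1]
    if mode == "periodic" and len(x) % 2 == 1:
        x = np.concatenate([x, x[-1:]])  # repeat last sample to even length
    n = len(x)
    ext = _extend(x, L - 1, mode)
    if mode == "symmetric":
        out_len = (n + L - 1) // 2
        offset = L
    else:
        out_len = n // 2
        offset = 3 * L // 2 - 1
    conv_lo = np.convolve(ext, dec_lo)
    conv_hi = np.convolve(ext, dec_hi)
    cA = conv_lo[offset::2][:out_len]
    cD = conv_hi[offset::2][:out_len]
    return cA, cD


def _idwt_single(cA, cD, filters: WaveletFilterPair, mode: str, out_len: int):
    """One synthesis step: upsample, convolve with synthesis pair, sum, trim."""
    L = filters.L
    if cA is None:
        cA = np.zeros_like(cD)
    if cD is None:
        cD = np.zeros_like(cA)
    if len(cA) != len(cD):
        raise ValueError("approximation/detail length mismatch")
    nc = len(cA)
    upA = np.zeros(2 * nc)
    upA[::2] = cA
    upD = np.zeros(2 * nc)
    upD[::2] = cD
    full = np.convolve(upA, filters.lowpass) + np.convolve(upD, filters.highpass)
    if mode == "symmetric":
        rec = full[L - 2 : L - 2 + 2 * nc - L + 2]
    else:
        wrapped = np.zeros(2 * nc)
        np.add.at(wrapped, np.arange(len(full)) % (2 * nc), full)
        rec = np.roll(wrapped, -(L // 2 - 1))
    return rec[:out_len]


# -- pyramid -----------------------------------------------------------------

@dataclass
class CoefficientPyramid:
    """DWT coefficient pyramid: approximation at scale J, details at 1..J."""

    approx: np.ndarray
    details: list[np.ndarray]  # details[j-1] is level j (finest first)
    level_input_lengths: list[int]  # signal length entering each level 1..J
    filters: WaveletFilterPair
    mode: str

    @property
    def J(self) -> int:
        return len(self.details)

    @property
    def n(self) -> int:
        return self.level_input_lengths[0]

    def band_lengths(self) -> dict[str, int]:
        out = {f"h_{j + 1}": len(d) for j, d in enumerate(self.details)}
        out[f"l_{self.J}"] = len(self.approx)
        return out


@dataclass
class MRAComponents:
    """Additive multiresolution bands: ``signal = approximation + sum(details)``."""

    approximation: np.ndarray  # l_J, full input length
    details: list[np.ndarray]  # h_1..h_J, each full input length
    mode: str

    @property
    def J(self) -> int:
        return len(self.details)

    def component(self, name: str) -> np.ndarray:
        """Fetch a band by its conventional name, ``"l_J"`` or ``"h_j"``."""
        kind, _, num = name.partition("_")
        j = int(num)
        if kind == "l" and j == self.J:
            return self.approximation
        if kind == "h" and 1 <= j <= self.J:
            return self.details[j - 1]
        raise KeyError(f"no component {name!r} at J={self.J}")

    def reconstruct(self) -> np.ndarray:
        return self.approximation + sum(self.details)


def _validate_decompose_args(signal, filters, J, mode):
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if np.isnan(signal).any():
        raise ValueError("signal contains missing values; gap-fill before decomposing")
    if mode not in _MODES:
        raise ValueError(f"unknown extension mode {mode!r}; choose from {_MODES}")
    jmax = max_decomposition_level(len(signal), filters.L)
    if not 1 <= J <= jmax:
        raise ValueError(
            f"decomposition level {J} outside 1..{jmax} for n={len(signal)}, L={filters.L}"
        )
    return signal


def dwt_decompose(
    signal,
    filters: WaveletFilterPair,
    J: int,
    extension_mode: str = "symmetric",
) -> CoefficientPyramid:
    """Pyramid decomposition to scale ``J``.

    At each level the current approximation is extended, correlated with the
    lowpass and highpass filters, and downsampled by two; the recursion
    continues on the lowpass output.
    """
    signal = _validate_decompose_args(signal, filters, J, extension_mode)
    approx = signal
    details: list[np.ndarray] = []
    lengths: list[int] = []
    for _ in range(J):
        lengths.append(len(approx))
        approx, d = _dwt_single(approx, filters, extension_mode)
        details.append(d)
    return CoefficientPyramid(
        approx=approx,
        details=details,
        level_input_lengths=lengths,
        filters=filters,
        mode=extension_mode,
    )


def reconstruct(pyramid: CoefficientPyramid, keep: str | None = None) -> np.ndarray:
    """Invert the pyramid.

    With ``keep=None`` all bands are used (perfect reconstruction).  With
    ``keep="l_J"`` or ``keep="h_j"`` every other band is zeroed first, which
    yields that band's additive MRA component.
    """
    J = pyramid.J
    filters, mode = pyramid.filters, pyramid.mode
    keep_l = keep is None or keep == f"l_{J}"
    approx = pyramid.approx if keep_l else np.zeros_like(pyramid.approx)
    for j in range(J, 0, -1):
        d = pyramid.details[j - 1]
        if keep is not None and keep != f"h_{j}":
            d = np.zeros_like(d)
        out_len = pyramid.level_input_lengths[j - 1]
        approx = _idwt_single(approx, d, filters, mode, out_len)
    return approx


def mra_components(
    signal,
    filters: WaveletFilterPair,
    J: int,
    extension_mode: str = "symmetric",
) -> MRAComponents:
    """Additive MRA of ``signal`` at scale ``J``.

    Component ``j`` is the reconstruction using only band ``j``'s
    coefficients; by linearity of the synthesis bank the components sum back
    to the input.
    """
    pyr = dwt_decompose(signal, filters, J, extension_mode)
    approximation = reconstruct(pyr, keep=f"l_{J}")
    details = [reconstruct(pyr, keep=f"h_{j}") for j in range(1, J + 1)]
    return MRAComponents(approximation=approximation, details=details, mode=extension_mode)


# -- field <-> signal --------------------------------------------------------

def field_to_signal(fld: Field) -> np.ndarray:
    """Flatten a gap-free gridded field row-major to a 1-D signal."""
    if fld.missing.any():
        raise ValueError(
            f"field {fld.variable!r} has {int(fld.missing.sum())} missing cells; "
            "only gap-filled fields can be decomposed"
        )
    return fld.values.reshape(-1).astype(float)


def signal_to_field(signal, grid: GridSpec, variable: str = "", hour=None) -> Field:
    """Reshape a 1-D signal back onto ``grid`` (inverse of row-major flatten)."""
    signal = np.asarray(signal, dtype=float)
    if signal.size != grid.n_cells:
        raise ValueError(f"signal length {signal.size} != grid cell count {grid.n_cells}")
    values = signal.reshape(grid.n_rows, grid.n_cols)
    return Field(grid=grid, variable=variable, hour=hour, values=values,
                 missing=np.zeros_like(values, dtype=bool))
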