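"""Forward models: metabolite linear combination and wavelet baseline.

The metabolite model is built in the time domain,

    s(t_k) = exp(i phi) * exp(i 2 pi df t_k) * g(t_k; L) * sum_m a_m b_m(t_k),

with a Gaussian broadening envelope g(t; L) = exp(-(pi L t)^2 / (4 ln 2)) so
that ``L`` is the full width at half maximum (Hz) *added* to each line, and
returned as the frequency-domain spectrum (ascending-frequency order).

The baseline model lives directly in the frequency domain: the real and
imaginary channels are each the inverse discrete wavelet transform of a set
of approximation coefficients with all detail bands zeroed.  With an
orthonormal wavelet (Daubechies-4, periodized) at level 3 this constrains
the baseline to the smooth approximation subspace, well separated from the
narrow metabolite lines.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pywt

from .basis import BasisSet
from .grid import SpectralGrid

__all__ = [
    "MetabParams",
    "BaselineParams",
    "Spectrum",
    "WaveletBaselineModel",
    "metabolite_forward",
    "baseline_forward",
    "model_forward",
    "metabolite_fid_batch",
    "GAUSS_LN2",
    "DEFAULT_WAVELET",
    "DEFAULT_LEVEL",
    "DEFAULT_FIT_WINDOW_PPM",
]

GAUSS_LN2 = 4.0 * np.log(2.0)
DEFAULT_WAVELET = "db4"
DEFAULT_LEVEL = 4
#: Default analysis window: NAA (2.01 ppm) through Cho (3.20 ppm) with margin,
#: excluding residual water and lipid.
DEFAULT_FIT_WINDOW_PPM = (1.7, 4.2)


@dataclass
class MetabParams:
    """Per-voxel metabolite-model parameters.

    amplitudes are in basis-normalized units (contributed peak height),
    ordered as the basis names (Cho, Cr, NAA by default).
    """

    amplitudes: np.ndarray
    phase0_deg: float = 0.0
    freq_shift_hz: float = 0.0
    gauss_fwhm_hz: float = 0.0

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")
        if not -180.0 <= self.phase0_deg <= 180.0:
            raise ValueError("phase0_deg must lie in [-180, 180]")
        if self.gauss_fwhm_hz < 0:
            raise ValueError("gauss_fwhm_hz must be non-negative")


@dataclass
class BaselineParams:
    """Wavelet approximation coefficients of the baseline, per channel."""

    coeffs_real: np.ndarray
    coeffs_imag: np.ndarray
    wavelet_family: str = DEFAULT_WAVELET
    level: int = DEFAULT_LEVEL

    def __post_init__(self) -> None:
        self.coeffs_real = np.asarray(self.coeffs_real, dtype=float)
        self.coeffs_imag = np.asarray(self.coeffs_imag, dtype=float)
        if self.coeffs_real.shape != self.coeffs_imag.shape:
            raise ValueError("real/imaginary coefficient lengths differ")
        if self.level < 1:
            raise ValueError("level must be a positive integer")


@dataclass(frozen=True)
class Spectrum:
    """A frequency-domain voxel spectrum on a grid (ascending frequency)."""

    values: np.ndarray
    grid: SpectralGrid

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=np.complex128)
        )
        if self.values.shape != (self.grid.n_points,):
            raise ValueError("spectrum length does not match grid")
        if not np.all(np.isfinite(self.values.view(float))):
            raise ValueError("spectrum contains non-finite values")

    @property
    def fid(self) -> np.ndarray:
        """Time-domain signal (inverse FFT of the shifted spectrum)."""
        return np.fft.ifft(np.fft.ifftshift(self.values))


class WaveletBaselineModel:
    """Linear map from approximation coefficients to a length-n signal.

    Uses a periodized orthonormal DWT, so the synthesis matrix ``W`` has
    orthonormal columns: coefficient extraction is exactly ``W.T @ signal``
    and the round trip W @ (W.T @ s) is the identity on signals whose detail
    bands are zero.
    """

    def __init__(
        self,
        n_points: int,
        wavelet: str = DEFAULT_WAVELET,
        level: int = DEFAULT_LEVEL,
    ) -> None:
        self.n_points = int(n_points)
        self.wavelet = wavelet
        self.level = int(level)
        self.n_coeffs = n_points >> self.level
        if self.n_coeffs < pywt.Wavelet(wavelet).dec_len:
            raise ValueError("too few approximation coefficients for this wavelet")
        # Dense synthesis matrix, built once per (n, wavelet, level).
        self.synthesis = _synthesis_matrix(self.n_points, wavelet, self.level)

    def reconstruct(self, coeffs: np.ndarray) -> np.ndarray:
        coeffs = np.asarray(coeffs, dtype=float)
        if coeffs.shape[-1] != self.n_coeffs:
            raise ValueError(
                f"expected {self.n_coeffs} approximation coefficients, "
                f"got {coeffs.shape[-1]}"
            )
        return coeffs @ self.synthesis.T

    def extract(self, signal: np.ndarray) -> np.ndarray:
        """Approximation coefficients of a signal (adjoint of reconstruct)."""
        return np.asarray(signal, dtype=float) @ self.synthesis


@lru_cache(maxsize=8)
def _synthesis_matrix(n_points: int, wavelet: str, level: int) -> np.ndarray:
    n_coeffs = n_points >> level
    cols = np.zeros((n_points, n_coeffs))
    zero_details = [
        np.zeros(n_points >> (level - j)) for j in range(level)
    ]
    for k in range(n_coeffs):
        approx = np.zeros(n_coeffs)
        approx[k] = 1.0
        cols[:, k] = pywt.waverec(
            [approx, *zero_details], wavelet, mode="periodization"
        )
    return cols


def baseline_model_for(grid: SpectralGrid, params: BaselineParams) -> WaveletBaselineModel:
    return WaveletBaselineModel(grid.n_points, params.wavelet_family, params.level)


def metabolite_fid_batch(
    basis: BasisSet,
    amplitudes: np.ndarray,
    phase0_deg: np.ndarray,
    freq_shift_hz: np.ndarray,
    gauss_fwhm_hz: np.ndarray,
) -> np.ndarray:
    """Vectorized metabolite-model FIDs for a batch of parameter sets.

    ``amplitudes`` has shape (batch, n_metabolites); the other arguments are
    length-batch vectors.  Returns complex FIDs of shape (batch, n_points).
    """
    t = basis.grid.time_axis_s
    amplitudes = np.atleast_2d(np.asarray(amplitudes, dtype=float))
    u = amplitudes @ basis.fids
    phase = np.deg2rad(np.asarray(phase0_deg, dtype=float))[..., None]
    shift = np.asarray(freq_shift_hz, dtype=float)[..., None]
    fwhm = np.asarray(gauss_fwhm_hz, dtype=float)[..., None]
    envelope = np.exp(
        1j * phase + 2j * np.pi * shift * t - (np.pi * fwhm * t) ** 2 / GAUSS_LN2
    )
    return envelope * u


def metabolite_forward(
    basis: BasisSet, params: MetabParams, grid: SpectralGrid | None = None
) -> Spectrum:
    """Frequency-domain metabolite model for one parameter set."""
    grid = grid or basis.grid
    if grid is not basis.grid and grid != basis.grid:
        raise ValueError("basis was synthesized on a different grid")
    if params.amplitudes.shape != (basis.n_metabolites,):
        raise ValueError("amplitude count does not match basis")
    fid = metabolite_fid_batch(
        basis,
        params.amplitudes[None, :],
        np.array([params.phase0_deg]),
        np.array([params.freq_shift_hz]),
        np.array([params.gauss_fwhm_hz]),
    )[0]
    return Spectrum(np.fft.fftshift(np.fft.fft(fid)), grid)


def baseline_forward(params: BaselineParams, grid: SpectralGrid) -> Spectrum:
    """Frequency-domain baseline from per-channel approximation coefficients."""
    model = baseline_model_for(grid, params)
    real = model.reconstruct(params.coeffs_real)
    imag = model.reconstruct(params.coeffs_imag)
    return Spectrum(real + 1j * imag, grid)


def model_forward(
    basis: BasisSet,
    metab_params: MetabParams,
    baseline_params: BaselineParams,
    grid: SpectralGrid | None = None,
) -> Spectrum:
    """Complete forward model: metabolite spectrum plus baseline."""
    grid = grid or basis.grid
    metab = metabolite_forward(basis, metab_params, grid)
    base = baseline_forward(baseline_params, grid)
    return Spectrum(metab.values + base.values, grid)
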