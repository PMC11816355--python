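"""Spectral-axis geometry for EPSI voxel spectra.

A voxel spectrum is stored in ascending-frequency order: bin ``j`` sits at
frequency ``f_j = (j - n/2) * spectral_width_hz / n`` relative to the
transmitter, i.e. the zero-frequency bin is at index ``n // 2`` and maps to
the reference chemical shift (water, 4.70 ppm by default).  Display
convention (high ppm on the left) is a plotting concern and never enters the
numerics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SpectralGrid", "build_grid", "ppm_to_index"]


@dataclass(frozen=True)
class SpectralGrid:
    """Geometry of the complex spectral axis.

    Parameters
    ----------
    n_points:
        Number of complex samples; a power of two, at least 64.
    spectral_width_hz:
        Acquisition bandwidth in Hz; the dwell time is its reciprocal.
    transmitter_mhz:
        Transmitter (Larmor) frequency in MHz; converts Hz offsets to ppm.
    ref_ppm:
        Chemical shift assigned to the zero-frequency bin (water reference).
    """

    n_points: int = 512
    spectral_width_hz: float = 1250.0
    transmitter_mhz: float = 123.25
    ref_ppm: float = 4.70

    def __post_init__(self) -> None:
        if self.n_points < 64 or (self.n_points & (self.n_points - 1)) != 0:
            raise ValueError(
                f"n_points must be a power of two >= 64, got {self.n_points}"
            )
        if self.spectral_width_hz <= 0:
            raise ValueError("spectral_width_hz must be positive")
        if self.transmitter_mhz <= 0:
            raise ValueError("transmitter_mhz must be positive")

    @property
    def dwell_s(self) -> float:
        return 1.0 / self.spectral_width_hz

    @property
    def hz_per_bin(self) -> float:
        return self.spectral_width_hz / self.n_points

    @property
    def ppm_per_bin(self) -> float:
        return self.hz_per_bin / self.transmitter_mhz

    @property
    def time_axis_s(self) -> np.ndarray:
        """FID sampling times t_k = k / spectral_width_hz."""
        return np.arange(self.n_points) * self.dwell_s

    @property
    def freq_axis_hz(self) -> np.ndarray:
        """Ascending frequency offsets, spanning [-sw/2, +sw/2)."""
        return np.fft.fftshift(np.fft.fftfreq(self.n_points, d=self.dwell_s))

    @property
    def ppm_axis(self) -> np.ndarray:
        """Ascending ppm axis; strictly monotone increasing."""
        return self.ref_ppm + self.freq_axis_hz / self.transmitter_mhz

    @property
    def ppm_span(self) -> float:
        return self.spectral_width_hz / self.transmitter_mhz

    @property
    def center_index(self) -> int:
        return self.n_points // 2

    def ppm_to_hz(self, ppm: float) -> float:
        """Frequency offset (Hz) of a chemical shift relative to the reference."""
        return (ppm - self.ref_ppm) * self.transmitter_mhz

    def window_slice(self, ppm_lo: float, ppm_hi: float) -> slice:
        """Contiguous bin slice covering [ppm_lo, ppm_hi] (ascending order)."""
        if ppm_lo >= ppm_hi:
            raise ValueError("require ppm_lo < ppm_hi")
        axis = self.ppm_axis
        idx = np.nonzero((axis >= ppm_lo) & (axis <= ppm_hi))[0]
        if idx.size == 0:
            raise ValueError("empty spectral window")
        return slice(int(idx[0]), int(idx[-1]) + 1)


def build_grid(
    n_points: int = 512,
    spectral_width_hz: float = 1250.0,
    transmitter_mhz: float = 123.25,
    ref_ppm: float = 4.70,
) -> SpectralGrid:
    """Construct a :class:`SpectralGrid`, validating all arguments."""
    if n_points <= 0:
        raise ValueError("n_points must be positive")
    return SpectralGrid(
        n_points=int(n_points),
        spectral_width_hz=float(spectral_width_hz),
        transmitter_mhz=float(transmitter_mhz),
        ref_ppm=float(ref_ppm),
    )


def ppm_to_index(grid: SpectralGrid, ppm: float) -> int:
    """Nearest spectral-bin index of a chemical shift.

    Raises
    ------
    ValueError
        If ``ppm`` falls outside the grid's ppm span.
    """
    axis = grid.ppm_axis
    if ppm < axis[0] or ppm > axis[-1]:
        raise ValueError(
            f"ppm {ppm:g} outside grid span [{axis[0]:.3f}, {axis[-1]:.3f}]"
        )
    return int(np.argmin(np.abs(axis - ppm)))
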