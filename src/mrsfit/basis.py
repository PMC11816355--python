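"""Analytic metabolite basis synthesis.

Each metabolite is described by a small table of Lorentzian resonance lines
(chemical shift, relative amplitude, intrinsic linewidth).  The basis FID of
a metabolite is the sum of its lines' complex exponentials with Lorentzian
decay, scaled so that the magnitude spectrum peaks at exactly 1.  With that
normalization a fitted amplitude is (approximately) the contributed peak
height, which keeps ratio maps scale-free.

The default tables cover the three resonances quantified at long echo time:
choline (singlet at 3.20 ppm), creatine (3.03 ppm plus the 3.91 ppm CH2),
and N-acetyl aspartate (2.01 ppm singlet plus a weak aspartate multiplet
around 2.5-2.7 ppm).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .grid import SpectralGrid

__all__ = [
    "SpectralLine",
    "BasisSet",
    "DEFAULT_LINE_TABLES",
    "METABOLITES",
    "synthesize_basis",
    "default_basis",
    "read_line_table",
    "write_line_table",
]

METABOLITES = ("Cho", "Cr", "NAA")


@dataclass(frozen=True)
class SpectralLine:
    """One Lorentzian resonance line of a metabolite."""

    metabolite: str
    ppm: float
    rel_amplitude: float
    lorentz_width_hz: float

    def __post_init__(self) -> None:
        if self.rel_amplitude <= 0:
            raise ValueError("rel_amplitude must be positive")
        if self.lorentz_width_hz <= 0:
            raise ValueError("lorentz_width_hz must be positive")


#: Default line tables (ppm positions from the standard in-vivo assignments;
#: relative amplitudes and intrinsic widths are plausibility choices for a
#: long-TE 3 T acquisition).
DEFAULT_LINE_TABLES: Mapping[str, tuple[SpectralLine, ...]] = {
    "Cho": (SpectralLine("Cho", 3.20, 1.0, 4.0),),
    "Cr": (
        SpectralLine("Cr", 3.03, 1.0, 4.0),
        SpectralLine("Cr", 3.91, 0.7, 4.5),
    ),
    "NAA": (
        SpectralLine("NAA", 2.01, 1.0, 4.0),
        SpectralLine("NAA", 2.49, 0.08, 5.0),
        SpectralLine("NAA", 2.57, 0.10, 5.0),
        SpectralLine("NAA", 2.67, 0.08, 5.0),
    ),
}


@dataclass(frozen=True)
class BasisSet:
    """Unit-peak-normalized complex time-domain basis signals on one grid."""

    grid: SpectralGrid
    names: tuple[str, ...]
    fids: np.ndarray  # (n_metabolites, n_points) complex
    line_tables: Mapping[str, tuple[SpectralLine, ...]]

    def __post_init__(self) -> None:
        if self.fids.shape != (len(self.names), self.grid.n_points):
            raise ValueError("basis FID array shape inconsistent with grid/names")

    @property
    def n_metabolites(self) -> int:
        return len(self.names)

    def spectrum(self, name: str) -> np.ndarray:
        """Frequency-domain basis spectrum (ascending-frequency order)."""
        i = self.names.index(name)
        return np.fft.fftshift(np.fft.fft(self.fids[i]))

    def index(self, name: str) -> int:
        return self.names.index(name)


def synthesize_basis(
    grid: SpectralGrid,
    line_tables: Mapping[str, Sequence[SpectralLine]] | None = None,
) -> BasisSet:
    """Synthesize a unit-peak basis set from Lorentzian line tables.

    For each line, the FID contribution is

        rel_amplitude * exp(i 2 pi (ppm - ref_ppm) * transmitter * t)
                      * exp(-pi * lorentz_width_hz * t),

    summed over the metabolite's lines; the FID is then rescaled so the
    maximum magnitude of its spectrum equals 1.
    """
    if line_tables is None:
        line_tables = DEFAULT_LINE_TABLES
    if not line_tables or any(len(v) == 0 for v in line_tables.values()):
        raise ValueError("line table must contain at least one line per metabolite")

    t = grid.time_axis_s
    axis = grid.ppm_axis
    names = tuple(line_tables.keys())
    fids = np.zeros((len(names), grid.n_points), dtype=np.complex128)
    for i, name in enumerate(names):
        for line in line_tables[name]:
            if line.ppm < axis[0] or line.ppm > axis[-1]:
                raise ValueError(
                    f"line at {line.ppm} ppm outside grid span "
                    f"[{axis[0]:.3f}, {axis[-1]:.3f}]"
                )
            f_hz = grid.ppm_to_hz(line.ppm)
            fids[i] += (
                line.rel_amplitude
                * np.exp(2j * np.pi * f_hz * t)
                * np.exp(-np.pi * line.lorentz_width_hz * t)
            )
        peak = np.max(np.abs(np.fft.fft(fids[i])))
        fids[i] /= peak
    return BasisSet(grid=grid, names=names, fids=fids, line_tables=dict(
        (k, tuple(v)) for k, v in line_tables.items()
    ))


def default_basis(grid: SpectralGrid | None = None) -> BasisSet:
    """The Cho/Cr/NAA basis on the default grid (or a supplied one)."""
    return synthesize_basis(grid or SpectralGrid())


def write_line_table(
    line_tables: Mapping[str, Sequence[SpectralLine]], path: str | Path
) -> None:
    """Write line tables as whitespace-delimited text, one line per resonance."""
    with open(path, "w") as fh:
        fh.write("# metabolite ppm rel_amplitude lorentz_width_hz\n")
        for name, lines in line_tables.items():
            for ln in lines:
                fh.write(
                    f"{name} {ln.ppm:.4f} {ln.rel_amplitude:.6g} "
                    f"{ln.lorentz_width_hz:.6g}\n"
                )


def read_line_table(path: str | Path) -> dict[str, tuple[SpectralLine, ...]]:
    """Read line tables written by :func:`write_line_table`."""
    tables: dict[str, list[SpectralLine]] = {}
    with open(path) as fh:
        for raw in fh:
            raw = raw.strip()
            if not raw or raw.startswith("#"):
                continue
            parts = raw.split()
            if len(parts) != 4:
                raise ValueError(f"malformed line-table row: {raw!r}")
            name, ppm, amp, width = parts
            tables.setdefault(name, []).append(
                SpectralLine(name, float(ppm), float(amp), float(width))
            )
    return {k: tuple(v) for k, v in tables.items()}
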