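"""4D spectral volume container shared by the simulator, fitters and I/O."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import SpectralGrid

__all__ = ["SpectralVolume"]


@dataclass
class SpectralVolume:
    """A spatial grid of voxel spectra plus associated anatomical masks.

    ``spectra`` has shape (nx, ny, nz, n_points), complex, ascending
    frequency order along the last axis.  ``masks`` are boolean volumes of
    the spatial shape (brain, nawm, csf, cerebellum, brainstem, quality —
    quality is True where a voxel *passes* quality control).
    """

    spectra: np.ndarray
    grid: SpectralGrid
    voxel_dims_mm: tuple[float, float, float]
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.spectra.ndim != 4:
            raise ValueError("spectra must be a 4D (x, y, z, spectral) array")
        if self.spectra.shape[-1] != self.grid.n_points:
            raise ValueError("spectral axis length does not match grid")
        for name, mask in self.masks.items():
            if mask.shape != self.spatial_shape:
                raise ValueError(f"mask {name!r} shape does not match volume")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.spectra.shape[:3]

    @property
    def voxel_volume_ul(self) -> float:
        """Voxel volume in microliters (mm^3 == uL)."""
        return float(np.prod(self.voxel_dims_mm))

    def mask(self, name: str) -> np.ndarray:
        if name not in self.masks:
            raise KeyError(f"volume has no mask {name!r}")
        return self.masks[name]
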