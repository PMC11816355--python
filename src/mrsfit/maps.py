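"""Voxelwise fitting of spectral volumes into 3D parameter maps.

Both fitters — the neural model and the iterative least-squares reference —
are driven through one contract: given the flat array of brain-voxel
spectra they return per-voxel metabolite amplitudes, phase, frequency
shift, linewidth and reconstruction loss, which are scattered back into
dense 3D maps.  The Cho/NAA ratio map applies the 5%-quantile denominator
floor so near-empty voxels cannot blow the ratio up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .basis import BasisSet
from .lstsq import FitContext, fit_least_squares
from .network import FitModel, infer
from .volume import SpectralVolume

__all__ = ["MetaboliteMaps", "RatioMap", "fit_volume", "ratio_map"]


@dataclass
class MetaboliteMaps:
    """Dense 3D parameter maps; defined on ``fitted_mask`` voxels only."""

    amplitude: dict[str, np.ndarray]
    phase0_deg: np.ndarray
    freq_shift_hz: np.ndarray
    gauss_fwhm_hz: np.ndarray
    loss: np.ndarray
    fitted_mask: np.ndarray
    metabolites: tuple[str, ...]
    fitter: str = ""

    def __getitem__(self, name: str) -> np.ndarray:
        return self.amplitude[name]


@dataclass
class RatioMap:
    """Floored voxelwise metabolite ratio."""

    values: np.ndarray
    mask: np.ndarray
    floor_value: float
    floored_mask: np.ndarray
    numerator: str = ""
    denominator: str = ""


def fit_volume(
    fitter: FitModel | Literal["ls"],
    spectral_volume: SpectralVolume,
    brain_mask: np.ndarray | None = None,
    basis: BasisSet | None = None,
    batch_size: int = 2048,
) -> MetaboliteMaps:
    """Fit every brain-mask voxel of a volume into parameter maps.

    ``fitter`` is either a (trained) :class:`FitModel` or the string
    ``"ls"`` for the iterative least-squares reference (which then requires
    ``basis``).  Voxels outside the mask are left unfitted (zero, excluded
    from ``fitted_mask``).  The result is independent of voxel order.
    """
    if brain_mask is None:
        brain_mask = spectral_volume.mask("brain")
    if brain_mask.shape != spectral_volume.spatial_shape:
        raise ValueError("brain mask shape does not match volume")
    if not np.any(brain_mask):
        raise ValueError("empty brain mask")

    voxels = np.argwhere(brain_mask)
    flat = np.asarray(
        spectral_volume.spectra[tuple(voxels.T)], dtype=np.complex128
    )

    if isinstance(fitter, FitModel):
        if fitter.grid != spectral_volume.grid:
            raise ValueError("model grid does not match volume grid")
        res = infer(fitter, flat, batch_size=batch_size)
        names = res.metabolites
        amps = np.clip(res.amplitudes, 0.0, None)
        phase, shift = res.phase0_deg, res.freq_shift_hz
        fwhm, loss = res.gauss_fwhm_hz, res.loss
        fitter_name = "nn"
    elif fitter == "ls":
        if basis is None:
            raise ValueError("least-squares fitting requires a basis")
        if basis.grid != spectral_volume.grid:
            raise ValueError("basis grid does not match volume grid")
        context = FitContext(basis)
        names = basis.names
        n = flat.shape[0]
        amps = np.empty((n, len(names)))
        phase = np.empty(n)
        shift = np.empty(n)
        fwhm = np.empty(n)
        loss = np.empty(n)
        for i in range(n):
            fit = fit_least_squares(flat[i], basis, context=context)
            amps[i] = fit.metab.amplitudes
            phase[i] = fit.metab.phase0_deg
            shift[i] = fit.metab.freq_shift_hz
            fwhm[i] = fit.metab.gauss_fwhm_hz
            loss[i] = fit.residual_norm**2 / max(fit.window_bins, 1)
        fitter_name = "ls"
    else:
        raise ValueError(f"unknown fitter {fitter!r}")

    shape = spectral_volume.spatial_shape
    idx = tuple(voxels.T)

    def scatter(values: np.ndarray) -> np.ndarray:
        out = np.zeros(shape)
        out[idx] = values
        return out

    return MetaboliteMaps(
        amplitude={name: scatter(amps[:, j]) for j, name in enumerate(names)},
        phase0_deg=scatter(phase),
        freq_shift_hz=scatter(shift),
        gauss_fwhm_hz=scatter(fwhm),
        loss=scatter(loss),
        fitted_mask=brain_mask.copy(),
        metabolites=tuple(names),
        fitter=fitter_name,
    )


def ratio_map(
    numerator_map: np.ndarray,
    denominator_map: np.ndarray,
    mask: np.ndarray,
    floor_quantile: float = 0.05,
    numerator: str = "Cho",
    denominator: str = "NAA",
) -> RatioMap:
    """Voxelwise ratio with the denominator floored at a low quantile.

    The floor is the ``floor_quantile`` quantile (linear interpolation
    between order statistics) of the denominator within ``mask``;
    denominators below it are clamped to the floor before dividing, so the
    ratio cannot become arbitrarily large as the denominator approaches
    zero.
    """
    if not 0.0 <= floor_quantile < 1.0:
        raise ValueError("floor_quantile must lie in [0, 1)")
    if numerator_map.shape != denominator_map.shape or mask.shape != numerator_map.shape:
        raise ValueError("maps and mask must share one shape")
    if not np.any(mask):
        raise ValueError("empty mask")

    denom_vals = denominator_map[mask]
    floor = float(np.quantile(denom_vals, floor_quantile))
    if floor <= 0.0 and np.all(denom_vals <= 0.0):
        raise ZeroDivisionError(
            "denominator is non-positive everywhere in the mask and the "
            "floor quantile does not lift it"
        )
    floored = mask & (denominator_map < floor)
    clamped = np.maximum(denominator_map, floor)
    values = np.zeros_like(numerator_map, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        values[mask] = numerator_map[mask] / clamped[mask]
    if not np.all(np.isfinite(values[mask])):
        raise ZeroDivisionError("ratio is non-finite inside the mask")
    return RatioMap(
        values=values,
        mask=mask.copy(),
        floor_value=floor,
        floored_mask=floored,
        numerator=numerator,
        denominator=denominator,
    )
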