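"""Automated radiation-target delineation from a Cho/NAA ratio map.

Implements the trial protocol: the mean ratio in contralateral
normal-appearing white matter (NAWM) defines the reference level; voxels at
or above twice that level are metabolically abnormal; poor-quality, CSF,
cerebellum and brainstem voxels are excluded; and the largest connected
component of what remains is the high-dose target surrogate.  The whole
chain is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .maps import RatioMap

__all__ = [
    "RTResult",
    "nawm_mean",
    "abnormality_mask",
    "apply_exclusions",
    "primary_component",
    "mask_volume_ml",
    "run_rt_pipeline",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class RTResult:
    """Binary treatment-target mask plus the scalars that produced it."""

    target_mask: np.ndarray
    nawm_mean: float
    threshold_value: float
    multiplier: float
    n_components_before_selection: int
    volume_ml: float
    voxel_volume_ul: float


def _as_ratio_values(ratio) -> np.ndarray:
    return ratio.values if isinstance(ratio, RatioMap) else np.asarray(ratio)


def nawm_mean(ratio_map, nawm_mask: np.ndarray) -> float:
    """Arithmetic mean of the ratio over the NAWM reference region."""
    values = _as_ratio_values(ratio_map)
    if nawm_mask.shape != values.shape:
        raise ValueError("NAWM mask shape does not match ratio map")
    if not np.any(nawm_mask):
        raise ValueError("empty NAWM mask")
    return float(values[nawm_mask].mean())


def abnormality_mask(ratio_map, nawm_reference: float, multiplier: float = 2.0) -> np.ndarray:
    """Voxels whose ratio is at least ``multiplier`` times the NAWM mean.

    The boundary is inclusive: a voxel exactly at the threshold is counted
    as abnormal.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    values = _as_ratio_values(ratio_map)
    mask = values >= multiplier * nawm_reference
    if isinstance(ratio_map, RatioMap):
        mask &= ratio_map.mask
    return mask


def apply_exclusions(
    mask: np.ndarray,
    quality_mask: np.ndarray,
    csf_mask: np.ndarray,
    cerebellum_mask: np.ndarray,
    brainstem_mask: np.ndarray,
) -> np.ndarray:
    """Remove poor-quality, CSF, cerebellum and brainstem voxels.

    ``quality_mask`` is True where a voxel passes quality control.
    """
    for other in (quality_mask, csf_mask, cerebellum_mask, brainstem_mask):
        if other.shape != mask.shape:
            raise ValueError("exclusion mask shape mismatch")
    return mask & quality_mask & ~csf_mask & ~cerebellum_mask & ~brainstem_mask


def primary_component(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Largest connected component of a binary volume (empty in, empty out).

    Ties on size are broken by the smallest flat index of a member voxel,
    which makes the selection deterministic.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    if n == 0:
        return np.zeros_like(mask, dtype=bool)
    sizes = np.bincount(labels.ravel())[1:]
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if best.size > 1:
        flat = labels.ravel()
        first = {int(lab): int(np.argmax(flat == lab)) for lab in best}
        chosen = min(first, key=first.get)
    else:
        chosen = int(best[0])
    return labels == chosen


def n_components(mask: np.ndarray, connectivity: int = 26) -> int:
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    return int(ndimage.label(mask, structure=_STRUCTURES[connectivity])[1])


def mask_volume_ml(mask: np.ndarray, voxel_volume_ul: float) -> float:
    """Mask volume in milliliters given the voxel volume in microliters."""
    if voxel_volume_ul <= 0:
        raise ValueError("voxel_volume_ul must be positive")
    return float(np.count_nonzero(mask) * voxel_volume_ul / 1000.0)


def run_rt_pipeline(
    ratio_map,
    masks: dict[str, np.ndarray],
    multiplier: float = 2.0,
    connectivity: int = 26,
    voxel_volume_ul: float = 107.666015625,
) -> RTResult:
    """NAWM reference -> threshold -> exclusions -> primary component -> volume.

    ``masks`` must provide 'nawm', 'quality', 'csf', 'cerebellum' and
    'brainstem' volumes co-registered with the ratio map.
    """
    required = ("nawm", "quality", "csf", "cerebellum", "brainstem")
    missing = [k for k in required if k not in masks]
    if missing:
        raise ValueError(f"missing masks: {missing}")
    reference = nawm_mean(ratio_map, masks["nawm"])
    abnormal = abnormality_mask(ratio_map, reference, multiplier)
    candidate = apply_exclusions(
        abnormal,
        masks["quality"],
        masks["csf"],
        masks["cerebellum"],
        masks["brainstem"],
    )
    n_comp = n_components(candidate, connectivity)
    target = primary_component(candidate, connectivity)
    return RTResult(
        target_mask=target,
        nawm_mean=reference,
        threshold_value=multiplier * reference,
        multiplier=multiplier,
        n_components_before_selection=n_comp,
        volume_ml=mask_volume_ml(target, voxel_volume_ul),
        voxel_volume_ul=voxel_volume_ul,
    )
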