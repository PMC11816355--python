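"""Agreement metrics between two fitters' outputs.

SSIM is computed in 3D with a uniform-weight cubic window restricted to the
analysis mask (local means, variances and covariance are renormalized by
the number of in-mask voxels under the window, with the usual sample
covariance correction); the dynamic range is the joint min-max within the
mask.  Dice of two empty masks is defined as 1 (trivially perfect
agreement).  Bland-Altman limits are bias +/- 1.96 sample standard
deviations of the paired differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "AgreementReport",
    "ssim",
    "pearson",
    "dice",
    "bland_altman",
    "compute_agreement",
    "export_reports",
]


def ssim(
    map_a: np.ndarray,
    map_b: np.ndarray,
    mask: np.ndarray | None = None,
    window: int = 7,
    k1: float = 0.01,
    k2: float = 0.03,
    return_map: bool = False,
):
    """Mean local structural similarity over mask voxels.

    ``window`` is the cubic window edge length (odd).  Local statistics use
    only in-mask voxels under the window; windows with fewer than two mask
    voxels are skipped.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must share one shape")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    if mask.shape != a.shape:
        raise ValueError("mask shape does not match maps")
    if not np.any(mask):
        raise ValueError("empty mask")
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")

    lo = min(a[mask].min(), b[mask].min())
    hi = max(a[mask].max(), b[mask].max())
    dynamic_range = hi - lo
    if dynamic_range == 0.0:
        # both maps constant and equal within the mask
        value = 1.0
        if return_map:
            smap = np.where(mask, 1.0, np.nan)
            return value, smap
        return value

    m = mask.astype(float)
    size = (window,) * a.ndim

    def filt(x):
        return ndimage.uniform_filter(x, size=size, mode="constant", cval=0.0)

    win_n = float(window**a.ndim)
    counts = filt(m) * win_n
    valid = mask & (counts >= 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(counts > 0, 1.0 / np.maximum(counts, 1e-12), 0.0) * win_n
        mu_a = filt(a * m) * inv
        mu_b = filt(b * m) * inv
        # sample (n-1) normalization, as in the standard SSIM convention
        bessel = counts / np.maximum(counts - 1.0, 1e-12)
        var_a = (filt(a * a * m) * inv - mu_a**2) * bessel
        var_b = (filt(b * b * m) * inv - mu_b**2) * bessel
        cov = (filt(a * b * m) * inv - mu_a * mu_b) * bessel

    c1 = (k1 * dynamic_range) ** 2
    c2 = (k2 * dynamic_range) ** 2
    num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (var_a + var_b + c2)
    smap = np.full(a.shape, np.nan)
    smap[valid] = num[valid] / den[valid]
    value = float(np.nanmean(smap[mask]))
    if return_map:
        return value, smap
    return value


def pearson(values_a, values_b) -> float:
    """Product-moment correlation of two paired value sequences."""
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("paired inputs must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 paired values")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(np.corrcoef(a, b)[0, 1])


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A&B| / (|A| + |B|); two empty masks agree perfectly."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share one shape")
    total = a.sum() + b.sum()
    if total == 0:
        return 1.0
    return float(2.0 * np.count_nonzero(a & b) / total)


def bland_altman(values_a, values_b) -> tuple[float, float, float]:
    """(bias, lower limit, upper limit) of the paired differences a - b.

    Limits of agreement are bias +/- 1.96 sample standard deviations.
    """
    a = np.asarray(values_a, dtype=float).ravel()
    b = np.asarray(values_b, dtype=float).ravel()
    if a.size != b.size or a.size < 2:
        raise ValueError("need at least 2 paired values")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


@dataclass
class AgreementReport:
    """Per-scan agreement between two fitters."""

    scan_id: str
    ssim_per_metabolite: dict[str, float]
    ssim_ratio: float
    dice_target: float
    bland_altman_per_metabolite: dict[str, tuple[float, float, float]]
    volume_a_ml: float
    volume_b_ml: float

    def to_row(self) -> dict:
        row: dict = {"scan_id": self.scan_id, "ssim_ratio": self.ssim_ratio,
                     "dice_target": self.dice_target,
                     "volume_a_ml": self.volume_a_ml,
                     "volume_b_ml": self.volume_b_ml}
        for name, v in self.ssim_per_metabolite.items():
            row[f"ssim_{name}"] = v
        for name, (bias, lo, hi) in self.bland_altman_per_metabolite.items():
            row[f"ba_bias_{name}"] = bias
            row[f"ba_lo_{name}"] = lo
            row[f"ba_hi_{name}"] = hi
        return row


def compute_agreement(
    maps_a,
    maps_b,
    ratio_a,
    ratio_b,
    rt_a,
    rt_b,
    mask: np.ndarray | None = None,
    scan_id: str = "",
    max_ba_points: int = 20000,
    seed: int = 0,
) -> AgreementReport:
    """Full agreement report between two fitters' outputs on one scan.

    ``maps_*`` are :class:`~mrsfit.maps.MetaboliteMaps`, ``ratio_*`` are
    :class:`~mrsfit.maps.RatioMap` and ``rt_*`` are
    :class:`~mrsfit.rt.RTResult`.  Bland-Altman statistics are computed on
    voxel values inside the mask, subsampled to ``max_ba_points``.
    """
    if mask is None:
        mask = maps_a.fitted_mask & maps_b.fitted_mask
    rng = np.random.default_rng(seed)
    idx = np.flatnonzero(mask.ravel())
    if idx.size > max_ba_points:
        idx = rng.choice(idx, size=max_ba_points, replace=False)

    ssim_m = {}
    ba = {}
    for name in maps_a.metabolites:
        ssim_m[name] = ssim(maps_a[name], maps_b[name], mask)
        ba[name] = bland_altman(
            maps_a[name].ravel()[idx], maps_b[name].ravel()[idx]
        )
    return AgreementReport(
        scan_id=scan_id,
        ssim_per_metabolite=ssim_m,
        ssim_ratio=ssim(ratio_a.values, ratio_b.values, mask),
        dice_target=dice(rt_a.target_mask, rt_b.target_mask),
        bland_altman_per_metabolite=ba,
        volume_a_ml=rt_a.volume_ml,
        volume_b_ml=rt_b.volume_ml,
    )


def export_reports(reports: list[AgreementReport], path) -> pd.DataFrame:
    """Write one delimited row per scan; returns the assembled frame."""
    frame = pd.DataFrame([r.to_row() for r in reports])
    frame.to_csv(path, sep="\t", index=False)
    return frame
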