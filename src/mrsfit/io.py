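"""Readers/writers for the spectral container, NIfTI maps and dataset splits.

The spectral container is an HDF5 layout: ``/spectra`` (4D complex),
grid attributes on the root group, boolean masks under ``/masks/<name>``
and optional ground truth under ``/truth/<field>``.  Maps and masks travel
as NIfTI with voxel spacing in the affine; the default spacing follows from
FOV / matrix (280/64, 280/64, 180/32 mm).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .grid import SpectralGrid
from .synth import GroundTruth
from .volume import SpectralVolume

__all__ = [
    "FormatError",
    "ScanRecord",
    "SplitResult",
    "write_container",
    "read_container",
    "write_map_nifti",
    "read_map_nifti",
    "split_dataset",
]

DEFAULT_VOXEL_DIMS_MM = (280.0 / 64, 280.0 / 64, 180.0 / 32)


class FormatError(RuntimeError):
    """A container or map file is missing members or unreadable."""


# ------------------------- spectral container ------------------------------

_TRUTH_FIELDS = (
    "voxel_index", "amplitudes", "phase0_deg", "freq_shift_hz",
    "gauss_fwhm_hz", "coeffs_real", "coeffs_imag",
)


def write_container(
    spectral_volume: SpectralVolume,
    path: str | Path,
    ground_truth: GroundTruth | None = None,
) -> None:
    """Write a spectral volume (plus masks and optional truth) to HDF5."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset(
            "spectra", data=spectral_volume.spectra, compression="gzip",
            compression_opts=1,
        )
        fh.attrs["n_points"] = spectral_volume.grid.n_points
        fh.attrs["spectral_width_hz"] = spectral_volume.grid.spectral_width_hz
        fh.attrs["transmitter_mhz"] = spectral_volume.grid.transmitter_mhz
        fh.attrs["ref_ppm"] = spectral_volume.grid.ref_ppm
        fh.attrs["voxel_dims_mm"] = np.asarray(spectral_volume.voxel_dims_mm)
        masks = fh.create_group("masks")
        for name, mask in spectral_volume.masks.items():
            masks.create_dataset(name, data=mask, compression="gzip",
                                 compression_opts=1)
        if ground_truth is not None:
            tg = fh.create_group("truth")
            for key in _TRUTH_FIELDS:
                tg.create_dataset(key, data=getattr(ground_truth, key))
            tg.create_dataset(
                "region",
                data=np.array([s.encode() for s in ground_truth.region]),
            )
            tg.attrs["metabolites"] = list(ground_truth.metabolites)


def read_container(
    path: str | Path,
) -> tuple[SpectralVolume, GroundTruth | None]:
    """Read a container; returns the volume and (if present) ground truth."""
    try:
        fh = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"cannot open container {path}: {exc}") from exc
    with fh:
        for member in ("spectra", "masks"):
            if member not in fh:
                raise FormatError(f"container missing member {member!r}")
        for attr in ("n_points", "spectral_width_hz", "transmitter_mhz",
                     "ref_ppm", "voxel_dims_mm"):
            if attr not in fh.attrs:
                raise FormatError(f"container missing attribute {attr!r}")
        grid = SpectralGrid(
            n_points=int(fh.attrs["n_points"]),
            spectral_width_hz=float(fh.attrs["spectral_width_hz"]),
            transmitter_mhz=float(fh.attrs["transmitter_mhz"]),
            ref_ppm=float(fh.attrs["ref_ppm"]),
        )
        masks = {name: fh["masks"][name][()].astype(bool) for name in fh["masks"]}
        volume = SpectralVolume(
            spectra=fh["spectra"][()],
            grid=grid,
            voxel_dims_mm=tuple(fh.attrs["voxel_dims_mm"]),
            masks=masks,
        )
        truth = None
        if "truth" in fh:
            tg = fh["truth"]
            missing = [k for k in _TRUTH_FIELDS if k not in tg]
            if missing or "region" not in tg:
                raise FormatError(f"truth group missing members {missing}")
            amps = tg["amplitudes"][()]
            names = tuple(tg.attrs["metabolites"])
            voxels = tg["voxel_index"][()]
            maps = {}
            for j, name in enumerate(names):
                m = np.zeros(volume.spatial_shape)
                m[tuple(voxels.T)] = amps[:, j]
                maps[name] = m
            truth = GroundTruth(
                voxel_index=voxels,
                region=np.array([s.decode() for s in tg["region"][()]]),
                amplitudes=amps,
                phase0_deg=tg["phase0_deg"][()],
                freq_shift_hz=tg["freq_shift_hz"][()],
                gauss_fwhm_hz=tg["gauss_fwhm_hz"][()],
                coeffs_real=tg["coeffs_real"][()],
                coeffs_imag=tg["coeffs_imag"][()],
                metabolites=names,
                maps=maps,
            )
    return volume, truth


# ------------------------- fitted-maps container ---------------------------

def write_fits_container(maps, masks: dict, voxel_dims_mm, path) -> None:
    """Write fitted parameter maps (plus masks) to HDF5."""
    from .maps import MetaboliteMaps  # local import to keep io standalone

    assert isinstance(maps, MetaboliteMaps)
    with h5py.File(path, "w") as fh:
        fh.attrs["voxel_dims_mm"] = np.asarray(voxel_dims_mm)
        fh.attrs["metabolites"] = list(maps.metabolites)
        fh.attrs["fitter"] = maps.fitter
        g = fh.create_group("maps")
        for name in maps.metabolites:
            g.create_dataset(name, data=maps.amplitude[name])
        for name in ("phase0_deg", "freq_shift_hz", "gauss_fwhm_hz", "loss"):
            g.create_dataset(name, data=getattr(maps, name))
        g.create_dataset("fitted_mask", data=maps.fitted_mask)
        mg = fh.create_group("masks")
        for name, mask in masks.items():
            mg.create_dataset(name, data=mask, compression="gzip",
                              compression_opts=1)


def read_fits_container(path):
    """Read fitted maps; returns (MetaboliteMaps, masks, voxel_dims_mm)."""
    from .maps import MetaboliteMaps

    try:
        fh = h5py.File(path, "r")
    except OSError as exc:
        raise FormatError(f"cannot open fits container {path}: {exc}") from exc
    with fh:
        if "maps" not in fh:
            raise FormatError("fits container missing member 'maps'")
        g = fh["maps"]
        names = tuple(fh.attrs["metabolites"])
        maps = MetaboliteMaps(
            amplitude={name: g[name][()] for name in names},
            phase0_deg=g["phase0_deg"][()],
            freq_shift_hz=g["freq_shift_hz"][()],
            gauss_fwhm_hz=g["gauss_fwhm_hz"][()],
            loss=g["loss"][()],
            fitted_mask=g["fitted_mask"][()].astype(bool),
            metabolites=names,
            fitter=str(fh.attrs.get("fitter", "")),
        )
        masks = {name: fh["masks"][name][()].astype(bool)
                 for name in fh.get("masks", {})}
        voxel_dims = tuple(fh.attrs["voxel_dims_mm"])
    return maps, masks, voxel_dims


# ------------------------- NIfTI maps --------------------------------------

def write_map_nifti(
    map3d: np.ndarray,
    voxel_dims_mm: tuple[float, float, float],
    path: str | Path,
) -> None:
    """Write a 3D map (or mask) as NIfTI with the given voxel spacing."""
    map3d = np.asarray(map3d)
    if map3d.ndim != 3:
        raise ValueError("map must be 3D")
    if any(v <= 0 for v in voxel_dims_mm):
        raise ValueError("voxel dimensions must be positive")
    affine = np.diag([*voxel_dims_mm, 1.0])
    img = nib.Nifti1Image(map3d.astype(np.float64), affine)
    img.header.set_zooms(voxel_dims_mm)
    nib.save(img, str(path))


def read_map_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    """Read a 3D NIfTI map; returns (values, voxel dims in mm)."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several error types
        raise FormatError(f"cannot read NIfTI {path}: {exc}") from exc
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D map in {path}, got {data.ndim}D")
    return data, tuple(float(z) for z in img.header.get_zooms()[:3])


# ------------------------- dataset split -----------------------------------

@dataclass(frozen=True)
class ScanRecord:
    """One scan of one subject (a subject may have several scans)."""

    subject_id: str
    scan_id: str
    site: str = ""
    path: str = ""


@dataclass
class SplitResult:
    train: list[ScanRecord]
    test: list[ScanRecord]
    seed: int

    @property
    def train_subjects(self) -> set[str]:
        return {r.subject_id for r in self.train}

    @property
    def test_subjects(self) -> set[str]:
        return {r.subject_id for r in self.test}


def split_dataset(
    records: list[ScanRecord],
    n_test_subjects: int,
    seed: int = 0,
    n_test_scans: int | None = None,
) -> SplitResult:
    """Random subject-level split: all of a subject's scans travel together.

    When ``n_test_scans`` is given the seeded draw is repeated until the
    test subjects' scans total exactly that count, which reproduces a
    published split whose scan total is known; the search is deterministic
    for a given seed.
    """
    keys = set()
    for r in records:
        k = (r.subject_id, r.scan_id)
        if k in keys:
            raise ValueError(f"duplicate (subject_id, scan_id): {k}")
        keys.add(k)
    subjects = sorted({r.subject_id for r in records})
    if n_test_subjects >= len(subjects):
        raise ValueError("n_test_subjects must be below the subject count")
    scans_per_subject = {
        s: sum(1 for r in records if r.subject_id == s) for s in subjects
    }
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for _ in range(100000):
        perm = rng.permutation(len(subjects))
        test_subjects = {subjects[i] for i in perm[:n_test_subjects]}
        total = sum(scans_per_subject[s] for s in test_subjects)
        if n_test_scans is None or total == n_test_scans:
            break
    else:
        raise ValueError(
            f"no {n_test_subjects}-subject subset with {n_test_scans} scans found"
        )
    train = [r for r in records if r.subject_id not in test_subjects]
    test = [r for r in records if r.subject_id in test_subjects]
    return SplitResult(train=train, test=test, seed=seed)
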