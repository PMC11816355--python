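"""Synthetic EPSI phantom and training-spectra generator.

Emulates the statistical structure the fitting method assumes: a brain
ellipsoid of voxels whose spectra follow the linear-combination model with
region-dependent metabolite levels (a tumor with elevated Cho and depleted
NAA, near-empty CSF, cerebellum/brainstem blocks in the inferior slices, a
contralateral NAWM reference box), smooth wavelet-subspace baselines, random
zero-order phase and frequency offsets, and additive complex Gaussian
noise.  Every voxel's generating parameters are recorded as ground truth.

The default geometry matches a whole-brain echo-planar acquisition with a
64 x 64 x 32 matrix over a 280 x 280 x 180 mm field of view.  Region
metabolite levels are in basis-normalized (peak-height) units and are
plausibility choices for long-TE brain spectra, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .basis import BasisSet, default_basis
from .grid import SpectralGrid
from .model import (
    GAUSS_LN2,
    BaselineParams,
    MetabParams,
    Spectrum,
    WaveletBaselineModel,
    model_forward,
)
from .volume import SpectralVolume

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "REGION_LABELS",
    "sample_voxel_params",
    "simulate_spectrum",
    "simulate_phantom",
    "make_training_set",
]

REGION_LABELS = ("tissue", "tumor", "csf", "cerebellum", "brainstem")

#: (mean, sd) of metabolite amplitudes in normal-appearing tissue.
_TISSUE_LEVELS = {"Cho": (0.35, 0.05), "Cr": (0.80, 0.08), "NAA": (1.00, 0.10)}


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and statistics of the synthetic phantom.

    Region geometry is expressed in fractions of the matrix dimensions so a
    scaled-down phantom keeps the same anatomy.  ``tumor_cho_multiplier``
    and ``tumor_naa_multiplier`` scale the tissue means inside the tumor
    (defaults 3 and 0.4: the true tumor Cho/NAA is ~7.5x the tissue level).
    """

    dims: tuple[int, int, int] = (64, 64, 32)
    fov_mm: tuple[float, float, float] = (280.0, 280.0, 180.0)
    brain_center: tuple[float, float, float] = (0.5, 0.5, 0.5625)
    brain_semi: tuple[float, float, float] = (0.25, 0.297, 0.344)
    tumor_center: tuple[float, float, float] = (0.406, 0.4375, 0.594)
    tumor_semi: tuple[float, float, float] = (0.078, 0.078, 0.094)
    nawm_box: tuple[tuple[float, float], ...] = (
        (0.625, 0.75), (0.344, 0.531), (0.50, 0.75))
    cerebellum_y: tuple[float, float] = (0.59, 0.78)
    cerebellum_z: tuple[float, float] = (0.22, 0.375)
    brainstem_box: tuple[tuple[float, float], ...] = (
        (0.44, 0.56), (0.44, 0.56), (0.22, 0.40))
    csf_shell_inner: float = 0.93
    quality_shell_inner: float = 0.80
    quality_bad_fraction: float = 0.08
    tissue_levels: dict = field(default_factory=lambda: dict(_TISSUE_LEVELS))
    tumor_cho_multiplier: float = 3.0
    tumor_naa_multiplier: float = 0.4
    cerebellum_cho_multiplier: float = 1.3
    cerebellum_naa_multiplier: float = 0.9
    csf_amplitude_sd: float = 0.02
    phase_range_deg: tuple[float, float] = (-180.0, 180.0)
    shift_range_hz: tuple[float, float] = (-20.0, 20.0)
    fwhm_range_hz: tuple[float, float] = (2.0, 8.0)
    baseline_scale: float = 0.3
    noise_sd: float = 0.05
    seed: int = 0

    @property
    def voxel_dims_mm(self) -> tuple[float, float, float]:
        return tuple(f / d for f, d in zip(self.fov_mm, self.dims))


@dataclass
class GroundTruth:
    """Per-voxel generating parameters of a simulated phantom.

    Flat arrays are aligned with ``voxel_index`` (the (n, 3) integer
    coordinates of synthesized brain voxels); the 3D maps are dense volumes
    with zeros outside the brain.
    """

    voxel_index: np.ndarray
    region: np.ndarray  # string labels, aligned with voxel_index
    amplitudes: np.ndarray  # (n, n_metabolites)
    phase0_deg: np.ndarray
    freq_shift_hz: np.ndarray
    gauss_fwhm_hz: np.ndarray
    coeffs_real: np.ndarray
    coeffs_imag: np.ndarray
    metabolites: tuple[str, ...]
    maps: dict[str, np.ndarray]  # dense 3D: one per metabolite

    def amplitude_map(self, name: str) -> np.ndarray:
        return self.maps[name]


# ------------------------- parameter sampling ------------------------------

def _region_levels(label: str, config: PhantomConfig) -> dict:
    levels = {k: tuple(v) for k, v in config.tissue_levels.items()}
    if label == "tumor":
        cho = levels["Cho"]
        naa = levels["NAA"]
        levels["Cho"] = (cho[0] * config.tumor_cho_multiplier, cho[1])
        levels["NAA"] = (naa[0] * config.tumor_naa_multiplier, naa[1])
    elif label == "cerebellum":
        cho = levels["Cho"]
        naa = levels["NAA"]
        levels["Cho"] = (cho[0] * config.cerebellum_cho_multiplier, cho[1])
        levels["NAA"] = (naa[0] * config.cerebellum_naa_multiplier, naa[1])
    elif label == "csf":
        levels = {k: (0.0, config.csf_amplitude_sd) for k in levels}
    elif label not in ("tissue", "brainstem"):
        raise ValueError(f"unknown region label {label!r}")
    return levels


def _sample_region_batch(
    label: str,
    n: int,
    config: PhantomConfig,
    rng: np.random.Generator,
    metabolites: tuple[str, ...],
    n_coeffs: int,
):
    """Vectorized draws of (metab, baseline) parameters for one region."""
    levels = _region_levels(label, config)
    amps = np.empty((n, len(metabolites)))
    for j, name in enumerate(metabolites):
        mean, sd = levels[name]
        if sd == 0.0:
            amps[:, j] = mean
        else:
            # truncated-at-zero normal (no atom at exactly zero)
            amps[:, j] = stats.truncnorm.rvs(
                -mean / sd, np.inf, loc=mean, scale=sd, size=n,
                random_state=rng,
            )
    phase = rng.uniform(*config.phase_range_deg, size=n)
    shift = rng.uniform(*config.shift_range_hz, size=n)
    fwhm = rng.uniform(*config.fwhm_range_hz, size=n)
    # Baseline approximation coefficients: a scaled random walk over the
    # coefficient index gives smooth, low-frequency baselines.
    step = config.baseline_scale / np.sqrt(n_coeffs)
    c_r = step * np.cumsum(rng.standard_normal((n, n_coeffs)), axis=1)
    c_i = step * np.cumsum(rng.standard_normal((n, n_coeffs)), axis=1)
    return amps, phase, shift, fwhm, c_r, c_i


def sample_voxel_params(
    region_label: str,
    phantom_config: PhantomConfig,
    rng: np.random.Generator,
    basis: BasisSet | None = None,
) -> tuple[MetabParams, BaselineParams]:
    """Draw one voxel's generating parameters for a region label."""
    basis = basis or default_basis(SpectralGrid())
    n_coeffs = WaveletBaselineModel(basis.grid.n_points).n_coeffs
    amps, phase, shift, fwhm, c_r, c_i = _sample_region_batch(
        region_label, 1, phantom_config, rng, basis.names, n_coeffs
    )
    metab = MetabParams(
        amplitudes=amps[0],
        phase0_deg=float(phase[0]),
        freq_shift_hz=float(shift[0]),
        gauss_fwhm_hz=float(fwhm[0]),
    )
    return metab, BaselineParams(c_r[0], c_i[0])


def simulate_spectrum(
    metab_params: MetabParams,
    baseline_params: BaselineParams,
    grid: SpectralGrid,
    basis: BasisSet,
    noise_sd: float,
    rng: np.random.Generator,
) -> Spectrum:
    """Forward-model spectrum plus i.i.d. complex Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    clean = model_forward(basis, metab_params, baseline_params, grid)
    if noise_sd == 0:
        return clean
    noise = noise_sd * (
        rng.standard_normal(grid.n_points)
        + 1j * rng.standard_normal(grid.n_points)
    )
    return Spectrum(clean.values + noise, grid)


# ------------------------- phantom ----------------------------------------

def _normalized_radius(config: PhantomConfig) -> np.ndarray:
    nx, ny, nz = config.dims
    ix, iy, iz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    r2 = np.zeros(config.dims)
    for coord, n, c, s in zip(
        (ix, iy, iz), config.dims, config.brain_center, config.brain_semi
    ):
        r2 += ((coord - c * n) / (s * n)) ** 2
    return np.sqrt(r2)


def _box_mask(dims, box) -> np.ndarray:
    mask = np.ones(dims, dtype=bool)
    grids = np.meshgrid(*(np.arange(d) for d in dims), indexing="ij")
    for coord, n, (lo, hi) in zip(grids, dims, box):
        mask &= (coord >= lo * n) & (coord <= hi * n)
    return mask


def build_region_masks(config: PhantomConfig) -> dict[str, np.ndarray]:
    """Boolean anatomy masks; all regions are subsets of ``brain``."""
    r = _normalized_radius(config)
    brain = r <= 1.0
    csf = brain & (r > config.csf_shell_inner)

    nx, ny, nz = config.dims
    ix, iy, iz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    t2 = np.zeros(config.dims)
    for coord, n, c, s in zip(
        (ix, iy, iz), config.dims, config.tumor_center, config.tumor_semi
    ):
        t2 += ((coord - c * n) / (max(s * n, 1e-9))) ** 2
    tumor = t2 <= 1.0
    if np.any(tumor & ~brain):
        raise ValueError("tumor region extends outside the brain")

    cerebellum = brain & ~tumor
    cerebellum &= (iy >= config.cerebellum_y[0] * ny) & (
        iy <= config.cerebellum_y[1] * ny
    )
    cerebellum &= (iz >= config.cerebellum_z[0] * nz) & (
        iz <= config.cerebellum_z[1] * nz
    )
    brainstem = _box_mask(config.dims, config.brainstem_box) & brain & ~tumor
    brainstem &= ~cerebellum
    cerebellum &= ~csf
    brainstem &= ~csf

    nawm = _box_mask(config.dims, config.nawm_box) & brain
    nawm &= ~(csf | tumor | cerebellum | brainstem)
    return {
        "brain": brain,
        "tumor": tumor,
        "csf": csf,
        "cerebellum": cerebellum,
        "brainstem": brainstem,
        "nawm": nawm,
    }


def _region_label_volume(masks: dict[str, np.ndarray]) -> np.ndarray:
    """Priority labeling: tumor > cerebellum > brainstem > csf > tissue."""
    labels = np.full(masks["brain"].shape, "", dtype="U10")
    labels[masks["brain"]] = "tissue"
    for name in ("csf", "brainstem", "cerebellum", "tumor"):
        labels[masks[name]] = name
    return labels


def simulate_phantom(
    phantom_config: PhantomConfig | None = None,
    grid: SpectralGrid | None = None,
    basis: BasisSet | None = None,
) -> tuple[SpectralVolume, GroundTruth, dict[str, np.ndarray]]:
    """Generate a full spectral volume with ground truth and masks."""
    config = phantom_config or PhantomConfig()
    grid = grid or SpectralGrid()
    basis = basis or default_basis(grid)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    masks = build_region_masks(config)
    labels = _region_label_volume(masks)
    n_coeffs = WaveletBaselineModel(grid.n_points).n_coeffs

    voxels = np.argwhere(masks["brain"])
    n_vox = voxels.shape[0]
    region = labels[masks["brain"]]

    amps = np.empty((n_vox, basis.n_metabolites))
    phase = np.empty(n_vox)
    shift = np.empty(n_vox)
    fwhm = np.empty(n_vox)
    c_r = np.empty((n_vox, n_coeffs))
    c_i = np.empty((n_vox, n_coeffs))
    for label in REGION_LABELS:
        sel = region == label
        n = int(sel.sum())
        if n == 0:
            continue
        out = _sample_region_batch(label, n, config, rng, basis.names, n_coeffs)
        amps[sel], phase[sel], shift[sel], fwhm[sel], c_r[sel], c_i[sel] = out

    spectra_flat = _synthesize_batch(
        grid, basis, amps, phase, shift, fwhm, c_r, c_i,
        config.noise_sd, rng,
    )
    vol = np.zeros(config.dims + (grid.n_points,), dtype=np.complex64)
    vol[tuple(voxels.T)] = spectra_flat.astype(np.complex64)

    # Quality mask: a random fraction of peripheral brain voxels fails QC.
    radius = _normalized_radius(config)
    quality = masks["brain"].copy()
    shell = masks["brain"] & (radius > config.quality_shell_inner)
    shell_idx = np.argwhere(shell)
    n_bad = int(round(config.quality_bad_fraction * shell_idx.shape[0]))
    if n_bad > 0:
        bad = shell_idx[rng.choice(shell_idx.shape[0], size=n_bad, replace=False)]
        quality[tuple(bad.T)] = False

    truth_maps = {}
    for j, name in enumerate(basis.names):
        m = np.zeros(config.dims)
        m[tuple(voxels.T)] = amps[:, j]
        truth_maps[name] = m

    truth = GroundTruth(
        voxel_index=voxels,
        region=region,
        amplitudes=amps,
        phase0_deg=phase,
        freq_shift_hz=shift,
        gauss_fwhm_hz=fwhm,
        coeffs_real=c_r,
        coeffs_imag=c_i,
        metabolites=basis.names,
        maps=truth_maps,
    )
    all_masks = dict(masks)
    all_masks["quality"] = quality
    volume = SpectralVolume(
        spectra=vol,
        grid=grid,
        voxel_dims_mm=config.voxel_dims_mm,
        masks=all_masks,
    )
    return volume, truth, all_masks


def _synthesize_batch(
    grid, basis, amps, phase, shift, fwhm, c_r, c_i, noise_sd, rng,
    chunk: int = 4096,
) -> np.ndarray:
    """Vectorized forward model + noise for flat parameter arrays."""
    n = amps.shape[0]
    W = WaveletBaselineModel(grid.n_points).synthesis
    t = grid.time_axis_s
    out = np.empty((n, grid.n_points), dtype=np.complex128)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        u = amps[lo:hi] @ basis.fids
        env = np.exp(
            1j * np.deg2rad(phase[lo:hi])[:, None]
            + 2j * np.pi * shift[lo:hi][:, None] * t
            - (np.pi * fwhm[lo:hi][:, None] * t) ** 2 / GAUSS_LN2
        )
        spec = np.fft.fftshift(np.fft.fft(env * u, axis=1), axes=1)
        spec += c_r[lo:hi] @ W.T + 1j * (c_i[lo:hi] @ W.T)
        if noise_sd > 0:
            spec += noise_sd * (
                rng.standard_normal(spec.shape)
                + 1j * rng.standard_normal(spec.shape)
            )
        out[lo:hi] = spec
    return out


# ------------------------- training corpus --------------------------------

#: Region mixture of the training corpus (fractions of spectra per stratum).
DEFAULT_STRATA = {
    "tissue": 0.60,
    "tumor": 0.12,
    "csf": 0.08,
    "cerebellum": 0.12,
    "brainstem": 0.08,
}


def make_training_set(
    n_spectra: int,
    phantom_config: PhantomConfig | None = None,
    rng: np.random.Generator | int | None = None,
    grid: SpectralGrid | None = None,
    basis: BasisSet | None = None,
    strata: dict[str, float] | None = None,
    noise_sd: float | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Region-stratified single-voxel spectra with a row-aligned truth table.

    Returns a (n_spectra, n_points) complex array and a DataFrame with one
    row per spectrum (region label, metabolite amplitudes, phase, shift,
    linewidth).
    """
    if n_spectra < 1:
        raise ValueError("n_spectra must be at least 1")
    config = phantom_config or PhantomConfig()
    grid = grid or SpectralGrid()
    basis = basis or default_basis(grid)
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(np.random.SeedSequence(
            config.seed if rng is None else int(rng)
        ))
    strata = strata or DEFAULT_STRATA
    if noise_sd is None:
        noise_sd = config.noise_sd

    total = sum(strata.values())
    counts = {k: int(round(n_spectra * v / total)) for k, v in strata.items()}
    first = next(iter(counts))
    counts[first] += n_spectra - sum(counts.values())

    n_coeffs = WaveletBaselineModel(grid.n_points).n_coeffs
    rows = []
    spectra = np.empty((n_spectra, grid.n_points), dtype=np.complex128)
    pos = 0
    for label in REGION_LABELS:
        n = counts.get(label, 0)
        if n == 0:
            continue
        amps, phase, shift, fwhm, c_r, c_i = _sample_region_batch(
            label, n, config, rng, basis.names, n_coeffs
        )
        spectra[pos : pos + n] = _synthesize_batch(
            grid, basis, amps, phase, shift, fwhm, c_r, c_i, noise_sd, rng
        )
        frame = pd.DataFrame(amps, columns=list(basis.names))
        frame.insert(0, "region", label)
        frame["phase0_deg"] = phase
        frame["freq_shift_hz"] = shift
        frame["gauss_fwhm_hz"] = fwhm
        rows.append(frame)
        pos += n
    truth = pd.concat(rows, ignore_index=True)
    return spectra, truth
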