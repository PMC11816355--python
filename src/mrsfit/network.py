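"""Self-supervised neural spectral fitter.

Two 1D residual encoders (one for metabolites, one for baseline) map a
2-channel (real/imaginary) spectrum to latent vectors; dense heads map the
latents to the parameters of the shared analytic decoder — the metabolite
linear-combination model and the wavelet baseline of :mod:`mrsfit.model`.
Training is self-supervised: the decoder reconstructs the (augmented) input
spectrum and the mean squared reconstruction error over the analysis window
is minimized.  Because the decoder is an analytic forward model, its
gradients with respect to the parameters are closed-form, and the encoders
are trained by ordinary backpropagation.

Estimated parameters respect their physical ranges by construction: a
softplus map keeps amplitudes and linewidth non-negative, and scaled tanh
maps bound the zero-order phase to [-180, 180] degrees and the frequency
shift to a configurable +/- range.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from .basis import BasisSet, SpectralLine, synthesize_basis
from .grid import SpectralGrid
from .model import (
    DEFAULT_FIT_WINDOW_PPM,
    GAUSS_LN2,
    BaselineParams,
    MetabParams,
    Spectrum,
    WaveletBaselineModel,
)
from .nn import Adam, Dense, ResNet1d

__all__ = [
    "EncoderSpec",
    "TrainConfig",
    "FitModel",
    "InferenceResult",
    "build_model",
    "augment",
    "reconstruction_loss",
    "train",
    "infer",
    "save_model",
    "load_model",
    "desk_scale_config",
]


@dataclass(frozen=True)
class EncoderSpec:
    """Architecture of each residual encoder."""

    base_filters: int = 16
    stages: int = 4
    blocks_per_stage: int = 2
    stem_kernel: int = 7
    block_kernel: int = 3
    latent_dim: int = 128

    def __post_init__(self) -> None:
        if self.latent_dim <= 0:
            raise ValueError("latent_dim must be positive")
        if self.base_filters <= 0 or self.stages <= 0 or self.blocks_per_stage <= 0:
            raise ValueError("encoder sizes must be positive")

    @property
    def stage_filters(self) -> tuple[int, ...]:
        """Filter widths per stage; doubles each stage (16, 32, 64, 128)."""
        return tuple(self.base_filters * 2**i for i in range(self.stages))


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    The defaults are the full-scale settings (learning rate 1e-4, batch 512,
    200 epochs, +/-180 degree phase and +/-20 Hz frequency augmentation).
    See :func:`desk_scale_config` for the reduced schedule used on small
    synthetic corpora.
    """

    learning_rate: float = 1e-4
    batch_size: int = 512
    epochs: int = 200
    phase_range_deg: tuple[float, float] = (-180.0, 180.0)
    freq_range_hz: tuple[float, float] = (-20.0, 20.0)
    seed: int = 0
    fit_window_ppm: tuple[float, float] = DEFAULT_FIT_WINDOW_PPM
    #: L2 penalty weight on baseline coefficients.  The metabolite and
    #: baseline subspaces overlap, so the decomposition needs a convention;
    #: penalizing baseline energy prefers the smallest baseline able to
    #: explain the data, mirroring the least-squares fitter's minimum-norm
    #: baseline.
    baseline_penalty: float = 0.01
    #: Fraction of final training steps whose weights are averaged into the
    #: released model (Polyak tail averaging; 0 disables).
    polyak_tail: float = 0.0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training configuration")
        for rng_pair in (self.phase_range_deg, self.freq_range_hz):
            if rng_pair[0] > rng_pair[1]:
                raise ValueError("augmentation ranges must be ordered (lo, hi)")


def desk_scale_config(seed: int = 0, epochs: int = 20) -> TrainConfig:
    """Reduced training schedule for small (tens-of-thousands) corpora.

    With ~20k spectra and 20 epochs the optimizer takes only ~1500 steps, so
    the peak learning rate is raised to 4e-3 and the batch reduced to 256;
    the augmentation ranges are unchanged.
    """
    return TrainConfig(
        learning_rate=4e-3, batch_size=256, epochs=epochs, seed=seed
    )


class FitModel:
    """Trained (or untrained) neural fitter bound to one grid and basis."""

    #: Bound on the magnitude of the estimated frequency shift (Hz).
    shift_max_hz = 30.0
    #: Softplus output scale for the Gaussian linewidth head (Hz).
    fwhm_scale_hz = 4.0
    #: ppm margin kept around the analysis window in the encoder input crop.
    crop_margin_ppm = 0.35
    #: Default number of phase/frequency views averaged at inference.  The
    #: model is trained to be equivariant under phase and frequency shifts,
    #: so re-estimating under a handful of fixed extra views and averaging
    #: the invariant parameters (amplitudes, linewidth) and the
    #: back-rotated phase/shift reduces estimation variance.
    infer_views = 8
    #: Fixed per-view phase (deg) / shift (Hz) offsets, shared by every
    #: spectrum so inference stays independent of batch composition.
    _view_table = [
        (-135.0, -15.0), (-90.0, 10.0), (-45.0, -5.0), (22.5, 17.5),
        (67.5, -17.5), (112.5, 5.0), (157.5, -10.0), (180.0, 15.0),
        (-157.5, 2.5), (-112.5, -12.5), (-67.5, 12.5), (-22.5, -2.5),
        (45.0, 7.5), (90.0, -7.5), (135.0, 20.0),
    ]

    def __init__(
        self,
        encoder_spec: EncoderSpec,
        grid: SpectralGrid,
        basis: BasisSet,
        fit_window_ppm: tuple[float, float] = DEFAULT_FIT_WINDOW_PPM,
        seed: int = 0,
    ) -> None:
        self.encoder_spec = encoder_spec
        self.grid = grid
        self.basis = basis
        self.fit_window_ppm = tuple(fit_window_ppm)
        self.window = grid.window_slice(*fit_window_ppm)
        margin = int(round(self.crop_margin_ppm / grid.ppm_per_bin))
        self.crop = slice(
            max(0, self.window.start - margin),
            min(grid.n_points, self.window.stop + margin),
        )
        self.wavelet_model = WaveletBaselineModel(grid.n_points)
        self.n_coeffs = self.wavelet_model.n_coeffs
        self.seed = int(seed)

        rng = np.random.default_rng(np.random.SeedSequence(seed))
        kw = dict(
            base_filters=encoder_spec.base_filters,
            stages=encoder_spec.stages,
            blocks_per_stage=encoder_spec.blocks_per_stage,
            stem_kernel=encoder_spec.stem_kernel,
            block_kernel=encoder_spec.block_kernel,
            latent_dim=encoder_spec.latent_dim,
            input_len=self.crop.stop - self.crop.start,
        )
        self.metab_encoder = ResNet1d(2, rng=rng, **kw)
        self.baseline_encoder = ResNet1d(2, rng=rng, **kw)
        # Small-scale output layers so the untrained decoder starts near the
        # middle of every bounded range.
        self.metab_head = Dense(
            encoder_spec.latent_dim, basis.n_metabolites + 3, rng, w_scale=0.1
        )
        self.baseline_head = Dense(
            encoder_spec.latent_dim, 2 * self.n_coeffs, rng, w_scale=0.1
        )
        self.modules = [
            self.metab_encoder, self.baseline_encoder,
            self.metab_head, self.baseline_head,
        ]
        self.train_provenance: dict = {}
        self.loss_history: list[float] = []

    # ---------------- parameter maps -----------------------------------
    @staticmethod
    def _softplus(x: np.ndarray) -> np.ndarray:
        return np.logaddexp(0.0, x)

    def _decode_heads(self, raw_metab: np.ndarray, raw_base: np.ndarray):
        """Map raw head outputs to physical parameters (float64)."""
        nm = self.basis.n_metabolites
        raw_metab = raw_metab.astype(np.float64)
        amps = self._softplus(raw_metab[:, :nm])
        phase_deg = 180.0 * np.tanh(raw_metab[:, nm])
        shift_hz = self.shift_max_hz * np.tanh(raw_metab[:, nm + 1])
        fwhm_hz = self.fwhm_scale_hz * self._softplus(raw_metab[:, nm + 2])
        coeffs = raw_base.astype(np.float64)
        c_r = coeffs[:, : self.n_coeffs]
        c_i = coeffs[:, self.n_coeffs :]
        return amps, phase_deg, shift_hz, fwhm_hz, c_r, c_i

    # ---------------- forward / decode ---------------------------------
    def _encode_input(self, spectra_norm: np.ndarray) -> np.ndarray:
        crop = spectra_norm[:, self.crop]
        return np.stack([crop.real, crop.imag], axis=-1).astype(np.float32)

    def _forward(self, spectra_norm: np.ndarray, training: bool):
        x = self._encode_input(spectra_norm)
        lat_m = self.metab_encoder.forward(x, training)
        lat_b = self.baseline_encoder.forward(x, training)
        raw_m = self.metab_head.forward(lat_m, training)
        raw_b = self.baseline_head.forward(lat_b, training)
        return raw_m, raw_b

    def _decode_spectrum(self, amps, phase_deg, shift_hz, fwhm_hz, c_r, c_i):
        """Batch forward model; returns model spectra and decode cache."""
        t = self.grid.time_axis_s
        u = amps @ self.basis.fids
        env = np.exp(
            1j * np.deg2rad(phase_deg)[:, None]
            + 2j * np.pi * shift_hz[:, None] * t
            - (np.pi * fwhm_hz[:, None] * t) ** 2 / GAUSS_LN2
        )
        s = env * u
        metab_spec = np.fft.fftshift(np.fft.fft(s, axis=1), axes=1)
        W = self.wavelet_model.synthesis
        base = c_r @ W.T + 1j * (c_i @ W.T)
        return metab_spec + base, (s, env)

    @staticmethod
    def _scale(spectra: np.ndarray) -> np.ndarray:
        """Per-spectrum normalization scale (maximum magnitude)."""
        return np.maximum(np.abs(spectra).max(axis=1), 1e-12)

    # ---------------- public API ----------------------------------------
    def _fit_single_view(self, spectra: np.ndarray) -> "InferenceResult":
        """One forward pass through encoders, heads and decoder."""
        scale = self._scale(spectra)
        norm = spectra / scale[:, None]
        raw_m, raw_b = self._forward(norm, training=False)
        amps, phase_deg, shift_hz, fwhm_hz, c_r, c_i = self._decode_heads(
            raw_m, raw_b
        )
        recon, _ = self._decode_spectrum(amps, phase_deg, shift_hz, fwhm_hz, c_r, c_i)
        diff = recon[:, self.window] - norm[:, self.window]
        loss = np.mean(diff.real**2 + diff.imag**2, axis=1)
        return InferenceResult(
            amplitudes=amps * scale[:, None],
            phase0_deg=phase_deg,
            freq_shift_hz=shift_hz,
            gauss_fwhm_hz=fwhm_hz,
            coeffs_real=c_r * scale[:, None],
            coeffs_imag=c_i * scale[:, None],
            loss=loss * scale**2,
            metabolites=self.basis.names,
        )

    def fit_batch(self, spectra: np.ndarray,
                  n_views: int | None = None) -> "InferenceResult":
        """Run inference on a (batch, n_points) complex spectral array.

        With ``n_views > 1`` (default :attr:`infer_views`) the spectrum is
        additionally re-estimated under fixed extra phase/frequency offsets
        (the transforms used for training augmentation) and the estimates
        are averaged: amplitudes and linewidth directly, phase and shift
        after subtracting the applied offset (phase via the circular mean).
        Baseline coefficients and the reconstruction loss are those of the
        untransformed view.  ``n_views=1`` is a plain single pass.
        """
        spectra = np.atleast_2d(np.asarray(spectra, dtype=np.complex128))
        if spectra.shape[1] != self.grid.n_points:
            raise ValueError("spectra length does not match model grid")
        if n_views is None:
            n_views = self.infer_views
        result = self._fit_single_view(spectra)
        if n_views <= 1:
            return result
        amps = result.amplitudes.copy()
        fwhm = result.gauss_fwhm_hz.copy()
        shift = result.freq_shift_hz.copy()
        phase_vec = np.exp(1j * np.deg2rad(result.phase0_deg))
        t = self.grid.time_axis_s
        fids = np.fft.ifft(np.fft.ifftshift(spectra, axes=1), axis=1)
        for phi, df in self._view_table[: n_views - 1]:
            aug = fids * np.exp(1j * np.deg2rad(phi) + 2j * np.pi * df * t)
            view = self._fit_single_view(
                np.fft.fftshift(np.fft.fft(aug, axis=1), axes=1)
            )
            amps += view.amplitudes
            fwhm += view.gauss_fwhm_hz
            shift += view.freq_shift_hz - df
            phase_vec = phase_vec + np.exp(
                1j * np.deg2rad(view.phase0_deg - phi)
            )
        return InferenceResult(
            amplitudes=amps / n_views,
            phase0_deg=np.rad2deg(np.angle(phase_vec)),
            freq_shift_hz=np.clip(shift / n_views, -self.shift_max_hz,
                                  self.shift_max_hz),
            gauss_fwhm_hz=fwhm / n_views,
            coeffs_real=result.coeffs_real,
            coeffs_imag=result.coeffs_imag,
            loss=result.loss,
            metabolites=self.basis.names,
        )

    # ---------------- training ------------------------------------------
    def train_on(self, spectra: np.ndarray, config: TrainConfig) -> "FitModel":
        """Self-supervised training on a (n, n_points) spectral array."""
        spectra = np.asarray(spectra, dtype=np.complex128)
        n = spectra.shape[0]
        if n < config.batch_size:
            raise ValueError("need at least one full batch of spectra")
        if tuple(config.fit_window_ppm) != self.fit_window_ppm:
            raise ValueError("training window differs from the model's window")
        fids = np.fft.ifft(np.fft.ifftshift(spectra, axes=1), axis=1)
        t = self.grid.time_axis_s
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
        opt = Adam(self.modules, lr=config.learning_rate)
        w = self.window
        w_len = w.stop - w.start
        # Linear warmup over the first 5% of steps, cosine decay to zero:
        # the config's learning_rate is the peak rate.
        steps_per_epoch = max((n - config.batch_size) // config.batch_size + 1, 1)
        total_steps = config.epochs * steps_per_epoch
        warmup = max(int(0.05 * total_steps), 1)
        step = 0
        self.loss_history = []
        # Polyak tail averaging: running mean of the weights over the final
        # stretch of the schedule smooths out minibatch noise.
        avg_start = int(np.ceil((1.0 - config.polyak_tail) * total_steps))
        avg_arrays: list[np.ndarray] | None = None
        n_avg = 0
        for epoch in range(config.epochs):
            perm = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n - config.batch_size + 1, config.batch_size):
                idx = perm[start : start + config.batch_size]
                batch_fid = fids[idx]
                phi = rng.uniform(*config.phase_range_deg, size=idx.size)
                df = rng.uniform(*config.freq_range_hz, size=idx.size)
                aug = batch_fid * np.exp(
                    1j * np.deg2rad(phi)[:, None] + 2j * np.pi * df[:, None] * t
                )
                target = np.fft.fftshift(np.fft.fft(aug, axis=1), axes=1)
                target /= self._scale(target)[:, None]
                if step < warmup:
                    opt.lr = config.learning_rate * (step + 1) / warmup
                else:
                    progress = (step - warmup) / max(total_steps - warmup, 1)
                    opt.lr = config.learning_rate * 0.5 * (
                        1.0 + np.cos(np.pi * progress)
                    )
                step += 1
                loss = self._train_step(target, opt, w, w_len,
                                        config.baseline_penalty)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}"
                    )
                epoch_loss += loss
                n_batches += 1
                if config.polyak_tail > 0 and step > avg_start:
                    current = self.state_arrays()
                    if avg_arrays is None:
                        avg_arrays = [a.astype(np.float64) for a in current]
                    else:
                        for acc, a in zip(avg_arrays, current):
                            acc += a
                    n_avg += 1
            self.loss_history.append(epoch_loss / max(n_batches, 1))
        if avg_arrays is not None and n_avg > 1:
            self.load_state_arrays(
                [(a / n_avg).astype(np.float32) for a in avg_arrays]
            )
        self.train_provenance = {
            "config": _config_dict(config),
            "n_spectra": int(n),
            "final_loss": float(self.loss_history[-1]),
        }
        return self

    def _train_step(self, target: np.ndarray, opt: Adam, w: slice,
                    w_len: int, baseline_penalty: float = 0.0) -> float:
        B = target.shape[0]
        nm = self.basis.n_metabolites
        raw_m, raw_b = self._forward(target, training=True)
        amps, phase_deg, shift_hz, fwhm_hz, c_r, c_i = self._decode_heads(raw_m, raw_b)
        recon, (s, env) = self._decode_spectrum(
            amps, phase_deg, shift_hz, fwhm_hz, c_r, c_i
        )
        diff = recon[:, w] - target[:, w]
        loss = float(np.mean(diff.real**2 + diff.imag**2))

        # Wirtinger gradient of the mean squared error wrt the model spectrum.
        G = np.zeros_like(recon)
        G[:, w] = (2.0 / (w_len * B)) * diff

        # Baseline path: the synthesis operator is linear.  The penalty term
        # (see TrainConfig.baseline_penalty) resolves the overlap between the
        # baseline subspace and broadened metabolite lines in favor of the
        # smallest baseline, like the least-squares fitter's min-norm choice.
        Ww = self.wavelet_model.synthesis[w, :]
        d_cr = G[:, w].real @ Ww
        d_ci = G[:, w].imag @ Ww
        if baseline_penalty > 0.0:
            d_cr += (2.0 * baseline_penalty / c_r.size) * c_r
            d_ci += (2.0 * baseline_penalty / c_i.size) * c_i

        # Metabolite path: adjoint FFT back to the time domain.
        n = self.grid.n_points
        ds = n * np.fft.ifft(np.fft.ifftshift(G, axes=1), axis=1)
        q = np.conj(ds) * s
        t = self.grid.time_axis_s
        d_amps = ((np.conj(ds) * env) @ self.basis.fids.T).real
        d_phase_rad = -q.imag.sum(axis=1)
        d_shift = -2.0 * np.pi * (q.imag @ t)
        d_fwhm = -(np.pi**2 / (GAUSS_LN2 / 2.0)) * fwhm_hz * (q.real @ t**2)

        # Chain through the bounding maps to the raw head outputs.
        raw64 = raw_m.astype(np.float64)
        d_raw_m = np.empty_like(raw64)
        d_raw_m[:, :nm] = d_amps * _sigmoid(raw64[:, :nm])
        d_raw_m[:, nm] = d_phase_rad * np.pi * (1.0 - np.tanh(raw64[:, nm]) ** 2)
        d_raw_m[:, nm + 1] = (
            d_shift * self.shift_max_hz * (1.0 - np.tanh(raw64[:, nm + 1]) ** 2)
        )
        d_raw_m[:, nm + 2] = (
            d_fwhm * self.fwhm_scale_hz * _sigmoid(raw64[:, nm + 2])
        )
        d_raw_b = np.concatenate([d_cr, d_ci], axis=1)

        d_lat_m = self.metab_head.backward(d_raw_m.astype(np.float32))
        d_lat_b = self.baseline_head.backward(d_raw_b.astype(np.float32))
        self.metab_encoder.backward(d_lat_m)
        self.baseline_encoder.backward(d_lat_b)
        opt.step()
        return loss

    # ---------------- serialization --------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        arrays = []
        for mod in self.modules:
            for leaf in (mod.walk() if hasattr(mod, "walk") else [mod]):
                arrays.extend(leaf.state())
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for mod in self.modules:
            for leaf in (mod.walk() if hasattr(mod, "walk") else [mod]):
                n = len(leaf.state())
                leaf.load_state([next(it) for _ in range(n)])

    def basis_fingerprint(self) -> str:
        return hashlib.sha1(
            np.ascontiguousarray(self.basis.fids).tobytes()
        ).hexdigest()


#: Backwards-friendly alias: a FitModel *is* the serializable model state.
FitModelState = FitModel


@dataclass
class InferenceResult:
    """Batched inference output; row order matches the input batch."""

    amplitudes: np.ndarray  # (n, n_metabolites), input units
    phase0_deg: np.ndarray
    freq_shift_hz: np.ndarray
    gauss_fwhm_hz: np.ndarray
    coeffs_real: np.ndarray
    coeffs_imag: np.ndarray
    loss: np.ndarray
    metabolites: tuple[str, ...]

    def __len__(self) -> int:
        return self.amplitudes.shape[0]

    def metab_params(self, i: int) -> MetabParams:
        return MetabParams(
            amplitudes=np.clip(self.amplitudes[i], 0.0, None),
            phase0_deg=float(self.phase0_deg[i]),
            freq_shift_hz=float(self.freq_shift_hz[i]),
            gauss_fwhm_hz=float(self.gauss_fwhm_hz[i]),
        )

    def baseline_params(self, i: int) -> BaselineParams:
        return BaselineParams(self.coeffs_real[i], self.coeffs_imag[i])


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _config_dict(config: TrainConfig) -> dict:
    d = asdict(config)
    d["phase_range_deg"] = list(d["phase_range_deg"])
    d["freq_range_hz"] = list(d["freq_range_hz"])
    d["fit_window_ppm"] = list(d["fit_window_ppm"])
    return d


# ------------------------- module-level operations ------------------------

def build_model(
    encoder_spec: EncoderSpec | None = None,
    grid: SpectralGrid | None = None,
    basis: BasisSet | None = None,
    fit_window_ppm: tuple[float, float] = DEFAULT_FIT_WINDOW_PPM,
    seed: int = 0,
) -> FitModel:
    """Construct an untrained fitter for a grid/basis pair."""
    if basis is None:
        grid = grid or SpectralGrid()
        basis = synthesize_basis(grid)
    grid = grid or basis.grid
    if grid != basis.grid:
        raise ValueError("grid does not match basis grid")
    return FitModel(encoder_spec or EncoderSpec(), grid, basis,
                    fit_window_ppm=fit_window_ppm, seed=seed)


def augment(
    spectrum: Spectrum,
    rng: np.random.Generator,
    config: TrainConfig,
) -> tuple[Spectrum, float, float]:
    """Apply a random phase and frequency shift to one spectrum.

    Returns the augmented spectrum together with the applied phase (deg) and
    frequency shift (Hz).  Degenerate ranges collapse to the identity.
    """
    phi = float(rng.uniform(*config.phase_range_deg))
    df = float(rng.uniform(*config.freq_range_hz))
    t = spectrum.grid.time_axis_s
    fid = spectrum.fid * np.exp(1j * np.deg2rad(phi) + 2j * np.pi * df * t)
    return (
        Spectrum(np.fft.fftshift(np.fft.fft(fid)), spectrum.grid),
        phi,
        df,
    )


def reconstruction_loss(spectrum, model_spectrum, fit_window) -> float:
    """Mean squared real+imaginary error over the analysis window.

    ``fit_window`` may be a slice, an integer index array / boolean mask, or
    a (lo, hi) ppm pair (the latter requires :class:`Spectrum` inputs).
    """
    a = spectrum.values if isinstance(spectrum, Spectrum) else np.asarray(spectrum)
    b = (
        model_spectrum.values
        if isinstance(model_spectrum, Spectrum)
        else np.asarray(model_spectrum)
    )
    if a.shape != b.shape:
        raise ValueError("spectra have different lengths")
    if isinstance(fit_window, tuple) and len(fit_window) == 2:
        if not isinstance(spectrum, Spectrum):
            raise ValueError("ppm window requires Spectrum inputs")
        fit_window = spectrum.grid.window_slice(*fit_window)
    diff = a[fit_window] - b[fit_window]
    if diff.size == 0:
        raise ValueError("empty fit window")
    return float(np.mean(diff.real**2 + diff.imag**2))


def train(
    spectra: np.ndarray,
    train_config: TrainConfig,
    encoder_spec: EncoderSpec | None = None,
    grid: SpectralGrid | None = None,
    basis: BasisSet | None = None,
) -> FitModel:
    """Build a model and train it self-supervised on a spectral array."""
    model = build_model(
        encoder_spec, grid, basis,
        fit_window_ppm=train_config.fit_window_ppm, seed=train_config.seed,
    )
    return model.train_on(spectra, train_config)


def infer(
    model: FitModel, spectra: np.ndarray, batch_size: int = 2048
) -> InferenceResult:
    """Batched inference; output order matches input order, weights untouched."""
    spectra = np.atleast_2d(np.asarray(spectra, dtype=np.complex128))
    if spectra.shape[1] != model.grid.n_points:
        raise ValueError("spectra length does not match model grid")
    parts = [
        model.fit_batch(spectra[i : i + batch_size])
        for i in range(0, spectra.shape[0], batch_size)
    ]
    if len(parts) == 1:
        return parts[0]
    return InferenceResult(
        amplitudes=np.concatenate([p.amplitudes for p in parts]),
        phase0_deg=np.concatenate([p.phase0_deg for p in parts]),
        freq_shift_hz=np.concatenate([p.freq_shift_hz for p in parts]),
        gauss_fwhm_hz=np.concatenate([p.gauss_fwhm_hz for p in parts]),
        coeffs_real=np.concatenate([p.coeffs_real for p in parts]),
        coeffs_imag=np.concatenate([p.coeffs_imag for p in parts]),
        loss=np.concatenate([p.loss for p in parts]),
        metabolites=model.basis.names,
    )


# ------------------------- checkpoint I/O ---------------------------------

def save_model(model: FitModel, path) -> None:
    """Serialize weights, config, grid and basis line tables to one file."""
    meta = {
        "encoder_spec": asdict(model.encoder_spec),
        "grid": asdict(model.grid),
        "fit_window_ppm": list(model.fit_window_ppm),
        "seed": model.seed,
        "train_provenance": model.train_provenance,
        "loss_history": model.loss_history,
        "basis_fingerprint": model.basis_fingerprint(),
        "line_tables": {
            name: [
                [ln.ppm, ln.rel_amplitude, ln.lorentz_width_hz]
                for ln in lines
            ]
            for name, lines in model.basis.line_tables.items()
        },
    }
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    with open(path, "wb") as fh:
        np.savez_compressed(fh, meta=np.bytes_(json.dumps(meta)), **arrays)


def load_model(path, grid: SpectralGrid | None = None) -> FitModel:
    """Load a checkpoint; refuses to load against a mismatched grid."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]))
        arrays = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
    ckpt_grid = SpectralGrid(**meta["grid"])
    if grid is not None and grid != ckpt_grid:
        raise ValueError("checkpoint grid does not match the requested grid")
    tables = {
        name: tuple(
            SpectralLine(name, ppm, amp, width)
            for ppm, amp, width in rows
        )
        for name, rows in meta["line_tables"].items()
    }
    basis = synthesize_basis(ckpt_grid, tables)
    model = FitModel(
        EncoderSpec(**meta["encoder_spec"]),
        ckpt_grid,
        basis,
        fit_window_ppm=tuple(meta["fit_window_ppm"]),
        seed=meta["seed"],
    )
    if model.basis_fingerprint() != meta["basis_fingerprint"]:
        raise ValueError("basis fingerprint mismatch in checkpoint")
    model.load_state_arrays(arrays)
    model.train_provenance = meta["train_provenance"]
    model.loss_history = list(meta["loss_history"])
    return model
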