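"""Neural fitter: architecture, augmentation, loss, training, inference."""

import numpy as np
import pytest

from mrsfit.model import Spectrum
from mrsfit.network import (
    EncoderSpec,
    TrainConfig,
    augment,
    build_model,
    infer,
    load_model,
    reconstruction_loss,
    save_model,
    train,
)
from mrsfit.nn import Adam
from mrsfit.synth import PhantomConfig, make_training_set

TINY_SPEC = EncoderSpec(base_filters=4, latent_dim=16)


def random_spectra(rng, n, n_points=512):
    s = rng.normal(size=(n, n_points)) + 1j * rng.normal(size=(n, n_points))
    return s / np.abs(s).max(axis=1, keepdims=True)


class TestArchitecture:
    def test_stage_filters_double_from_sixteen(self):
        assert EncoderSpec().stage_filters == (16, 32, 64, 128)

    def test_encoder_conv_widths_match_spec(self, grid, basis):
        from mrsfit.nn.layers import Conv1d

        model = build_model(EncoderSpec(), grid, basis)
        stem, *rest = [
            lf for lf in model.metab_encoder.walk() if isinstance(lf, Conv1d)
        ]
        assert stem.c_out == 16
        widths = sorted({c.c_out for c in rest})
        assert widths == [16, 32, 64, 128]

    def test_invalid_latent_dim_rejected(self):
        with pytest.raises(ValueError):
            EncoderSpec(latent_dim=0)

    def test_untrained_outputs_respect_bounds(self, grid, basis):
        model = build_model(TINY_SPEC, grid, basis, seed=1)
        res = model.fit_batch(random_spectra(np.random.default_rng(0), 16))
        assert np.all(res.amplitudes >= 0)
        assert np.all(np.abs(res.phase0_deg) <= 180.0)
        assert np.all(np.abs(res.freq_shift_hz) <= model.shift_max_hz)
        assert np.all(res.gauss_fwhm_hz >= 0)

    def test_inference_is_pure(self, grid, basis):
        model = build_model(TINY_SPEC, grid, basis, seed=1)
        x = random_spectra(np.random.default_rng(1), 8)
        r1 = model.fit_batch(x)
        r2 = model.fit_batch(x)
        assert np.array_equal(r1.amplitudes, r2.amplitudes)
        assert np.array_equal(r1.loss, r2.loss)


class TestAugment:
    def test_degenerate_ranges_are_identity(self, grid, basis):
        cfg = TrainConfig(phase_range_deg=(0, 0), freq_range_hz=(0, 0))
        rng = np.random.default_rng(0)
        s = Spectrum(random_spectra(rng, 1)[0], grid)
        out, phi, df = augment(s, rng, cfg)
        assert phi == 0.0 and df == 0.0
        assert np.allclose(out.values, s.values, atol=1e-12)

    def test_inverse_shift_restores_spectrum(self, grid):
        rng = np.random.default_rng(5)
        s = Spectrum(random_spectra(rng, 1)[0], grid)
        cfg_fwd = TrainConfig(phase_range_deg=(37.0, 37.0),
                              freq_range_hz=(11.0, 11.0))
        cfg_bwd = TrainConfig(phase_range_deg=(-37.0, -37.0),
                              freq_range_hz=(-11.0, -11.0))
        mid, _, _ = augment(s, rng, cfg_fwd)
        back, _, _ = augment(mid, rng, cfg_bwd)
        assert np.allclose(back.values, s.values, atol=1e-9)

    def test_pure_phase_shift_preserves_magnitude(self, grid):
        rng = np.random.default_rng(6)
        s = Spectrum(random_spectra(rng, 1)[0], grid)
        cfg = TrainConfig(phase_range_deg=(-120.0, -120.0),
                          freq_range_hz=(0.0, 0.0))
        out, _, _ = augment(s, rng, cfg)
        assert np.allclose(np.abs(out.values), np.abs(s.values), atol=1e-10)


class TestReconstructionLoss:
    def test_identical_spectra_have_zero_loss(self, grid):
        x = random_spectra(np.random.default_rng(2), 1)[0]
        assert reconstruction_loss(x, x, slice(0, 512)) == 0.0

    def test_quadratic_scaling(self):
        a = np.zeros(8, dtype=complex)
        b = np.full(8, 0.1 + 0.2j)
        l1 = reconstruction_loss(a, b, slice(0, 8))
        l3 = reconstruction_loss(a, 3 * b, slice(0, 8))
        assert l3 == pytest.approx(9 * l1)

    def test_four_bin_toy_value(self):
        """Residual (1, 0, 0, 0) in the real channel: mean of squares 0.25."""
        a = np.array([1.0, 0, 0, 0], dtype=complex)
        b = np.zeros(4, dtype=complex)
        assert reconstruction_loss(a, b, slice(0, 4)) == pytest.approx(0.25)

    def test_empty_window_rejected(self):
        a = np.zeros(8, dtype=complex)
        with pytest.raises(ValueError):
            reconstruction_loss(a, a, slice(4, 4))


@pytest.fixture(scope="module")
def tiny_corpus(grid, basis):
    spectra, _ = make_training_set(
        600, PhantomConfig(seed=2), rng=42, grid=grid, basis=basis
    )
    return spectra


class TestTraining:
    def test_loss_decreases_and_is_reproducible(self, grid, basis, tiny_corpus):
        cfg = TrainConfig(learning_rate=1e-3, batch_size=200, epochs=3, seed=7)
        m1 = train(tiny_corpus, cfg, TINY_SPEC, grid, basis)
        m2 = train(tiny_corpus, cfg, TINY_SPEC, grid, basis)
        assert m1.loss_history[-1] < m1.loss_history[0]
        assert m1.loss_history == m2.loss_history  # seeded determinism

    def test_checkpoint_round_trip(self, grid, basis, tiny_corpus, tmp_path):
        cfg = TrainConfig(learning_rate=1e-3, batch_size=200, epochs=1, seed=7)
        model = train(tiny_corpus, cfg, TINY_SPEC, grid, basis)
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        x = tiny_corpus[:8]
        r1 = model.fit_batch(x)
        r2 = loaded.fit_batch(x)
        assert np.array_equal(r1.amplitudes, r2.amplitudes)
        assert np.array_equal(r1.phase0_deg, r2.phase0_deg)

    def test_checkpoint_refuses_mismatched_grid(self, grid, basis, tiny_corpus,
                                                tmp_path):
        from mrsfit.grid import SpectralGrid

        cfg = TrainConfig(learning_rate=1e-3, batch_size=200, epochs=1, seed=7)
        model = train(tiny_corpus, cfg, TINY_SPEC, grid, basis)
        path = tmp_path / "model.npz"
        save_model(model, path)
        other = SpectralGrid(n_points=256)
        with pytest.raises(ValueError):
            load_model(path, grid=other)

    def test_gradient_matches_finite_difference(self, grid, basis):
        """Directional derivative of the end-to-end loss agrees with the
        assembled backprop gradient."""
        model = build_model(TINY_SPEC, grid, basis, seed=0)
        rng = np.random.default_rng(3)
        target = random_spectra(rng, 4)

        def loss_fn():
            raw_m, raw_b = model._forward(target, training=True)
            recon, _ = model._decode_spectrum(*model._decode_heads(raw_m, raw_b))
            d = recon[:, model.window] - target[:, model.window]
            return float(np.mean(d.real**2 + d.imag**2))

        opt = Adam(model.modules, lr=0.0)
        model._train_step(target, opt, model.window,
                          model.window.stop - model.window.start)
        params = [p for lf in opt.leaves for p in lf.params]
        grads = [g for lf in opt.leaves for g in lf.grads]
        gnorm = np.sqrt(sum(float((g.astype(np.float64) ** 2).sum())
                            for g in grads))
        eps = 1e-3
        saved = [p.copy() for p in params]
        for p, g in zip(params, grads):
            p -= (eps / gnorm) * g
        lo = loss_fn()
        for p, s in zip(params, saved):
            p[...] = s
        for p, g in zip(params, grads):
            p += (eps / gnorm) * g
        hi = loss_fn()
        for p, s in zip(params, saved):
            p[...] = s
        # central difference carries curvature and float32 noise at this
        # scale; 2% agreement rules out any sign/scale error in backprop
        assert (hi - lo) / (2 * eps) == pytest.approx(gnorm, rel=2e-2)


class TestInference:
    def test_batch_of_one_matches_row_of_large_batch(self, grid, basis):
        model = build_model(TINY_SPEC, grid, basis, seed=4)
        x = random_spectra(np.random.default_rng(9), 32)
        full = model.fit_batch(x)
        single = model.fit_batch(x[5:6])
        assert np.allclose(single.amplitudes[0], full.amplitudes[5])
        assert np.allclose(single.phase0_deg[0], full.phase0_deg[5])

    def test_permuting_batch_permutes_outputs(self, grid, basis):
        model = build_model(TINY_SPEC, grid, basis, seed=4)
        x = random_spectra(np.random.default_rng(10), 16)
        perm = np.random.default_rng(1).permutation(16)
        r = model.fit_batch(x)
        rp = model.fit_batch(x[perm])
        assert np.allclose(rp.amplitudes, r.amplitudes[perm])

    def test_infer_chunking_matches_single_pass(self, grid, basis):
        model = build_model(TINY_SPEC, grid, basis, seed=4)
        x = random_spectra(np.random.default_rng(11), 20)
        r1 = infer(model, x, batch_size=7)
        r2 = infer(model, x, batch_size=64)
        assert np.allclose(r1.amplitudes, r2.amplitudes)

    def test_grid_mismatch_rejected(self, grid, basis):
        model = build_model(TINY_SPEC, grid, basis, seed=4)
        with pytest.raises(ValueError):
            infer(model, np.zeros((2, 256), dtype=complex))
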