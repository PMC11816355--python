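"""Forward models: metabolite linear combination and wavelet baseline."""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st

from mrsfit.model import (
    BaselineParams,
    MetabParams,
    Spectrum,
    WaveletBaselineModel,
    baseline_forward,
    metabolite_forward,
    model_forward,
)


@pytest.fixture()
def params():
    return MetabParams(
        amplitudes=np.array([0.4, 0.8, 1.0]),
        phase0_deg=30.0,
        freq_shift_hz=5.0,
        gauss_fwhm_hz=4.0,
    )


N_COEFFS = WaveletBaselineModel(512).n_coeffs


@pytest.fixture()
def zero_baseline():
    return BaselineParams(np.zeros(N_COEFFS), np.zeros(N_COEFFS))


class TestMetabParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"amplitudes": np.array([-0.1, 1, 1])},
            {"amplitudes": np.ones(3), "phase0_deg": 200.0},
            {"amplitudes": np.ones(3), "gauss_fwhm_hz": -1.0},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        kwargs.setdefault("amplitudes", np.ones(3))
        with pytest.raises(ValueError):
            MetabParams(**kwargs)

    def test_mismatched_baseline_channels_rejected(self):
        with pytest.raises(ValueError):
            BaselineParams(np.zeros(N_COEFFS), np.zeros(N_COEFFS // 2))


class TestMetaboliteForward:
    def test_zero_amplitudes_give_zero_spectrum(self, basis):
        p = MetabParams(np.zeros(3), 10.0, 3.0, 2.0)
        s = metabolite_forward(basis, p)
        assert np.allclose(s.values, 0.0)

    @given(c=st.floats(0.0, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_linearity_in_amplitudes(self, basis, c):
        base = MetabParams(np.array([0.3, 0.7, 1.1]), 20.0, -4.0, 3.0)
        scaled = MetabParams(base.amplitudes * c, 20.0, -4.0, 3.0)
        s1 = metabolite_forward(basis, base).values
        s2 = metabolite_forward(basis, scaled).values
        assert np.allclose(s2, c * s1, atol=1e-10)

    def test_phase_180_negates_spectrum(self, basis):
        p0 = MetabParams(np.array([0.4, 0.8, 1.0]), 0.0, 0.0, 0.0)
        p180 = MetabParams(np.array([0.4, 0.8, 1.0]), 180.0, 0.0, 0.0)
        s0 = metabolite_forward(basis, p0).values
        s180 = metabolite_forward(basis, p180).values
        assert np.allclose(s180, -s0, atol=1e-12)

    def test_phase_round_trip_recovers_spectrum(self, basis, params):
        """Applying phase phi then unwinding by e^{-i phi} is the identity."""
        unphased = MetabParams(params.amplitudes, 0.0,
                               params.freq_shift_hz, params.gauss_fwhm_hz)
        s_phi = metabolite_forward(basis, params).values
        s_0 = metabolite_forward(basis, unphased).values
        unwound = s_phi * np.exp(-1j * np.deg2rad(params.phase0_deg))
        assert np.allclose(unwound, s_0, atol=1e-12)

    @pytest.mark.parametrize("k", [-8, -1, 1, 5])
    def test_integer_bin_shift_moves_peak_by_k_bins(self, grid, basis, k):
        shift = k * grid.hz_per_bin
        p0 = MetabParams(np.array([0.0, 0.0, 1.0]), 0.0, 0.0, 0.0)
        pk = MetabParams(np.array([0.0, 0.0, 1.0]), 0.0, shift, 0.0)
        j0 = np.argmax(np.abs(metabolite_forward(basis, p0).values))
        jk = np.argmax(np.abs(metabolite_forward(basis, pk).values))
        assert jk - j0 == k

    def test_gaussian_linewidth_broadens_isolated_line(self, grid, basis):
        def fwhm_bins(gauss_hz):
            p = MetabParams(np.array([1.0, 0.0, 0.0]), 0.0, 0.0, gauss_hz)
            mag = np.abs(metabolite_forward(basis, p).values)
            half = mag.max() / 2
            return np.count_nonzero(mag > half)

        widths = [fwhm_bins(g) for g in (0.0, 5.0, 10.0, 20.0)]
        assert widths == sorted(widths)
        assert widths[-1] > widths[0]

    def test_parseval_energy_consistency(self, grid, basis, params, zero_baseline):
        s = model_forward(basis, params, zero_baseline)
        fid = s.fid
        spec_energy = np.sum(np.abs(s.values) ** 2)
        fid_energy = np.sum(np.abs(fid) ** 2)
        assert spec_energy == pytest.approx(grid.n_points * fid_energy)


class TestBaselineForward:
    def test_zero_coefficients_give_zero_baseline(self, grid, zero_baseline):
        assert np.allclose(baseline_forward(zero_baseline, grid).values, 0.0)

    def test_round_trip_on_smooth_signal(self, grid):
        """Forward-DWT coefficients of an approximation-space signal
        reconstruct that signal exactly."""
        model = WaveletBaselineModel(grid.n_points)
        rng = np.random.default_rng(4)
        smooth_r = model.reconstruct(rng.normal(size=model.n_coeffs))
        smooth_i = model.reconstruct(rng.normal(size=model.n_coeffs))
        p = BaselineParams(model.extract(smooth_r), model.extract(smooth_i))
        out = baseline_forward(p, grid)
        assert np.allclose(out.values.real, smooth_r, atol=1e-12)
        assert np.allclose(out.values.imag, smooth_i, atol=1e-12)

    def test_one_hot_coefficient_matches_direct_idwt(self, grid):
        """A single unit approximation coefficient reproduces pywt's own
        inverse transform of that one-hot vector (independent oracle)."""
        model = WaveletBaselineModel(grid.n_points)
        k = 20
        one_hot = np.zeros(model.n_coeffs)
        one_hot[k] = 1.0
        coeffs = [one_hot] + [
            np.zeros(grid.n_points >> (model.level - j))
            for j in range(model.level)
        ]
        expected = pywt.waverec(coeffs, model.wavelet, mode="periodization")
        p = BaselineParams(one_hot, np.zeros(model.n_coeffs))
        assert np.allclose(baseline_forward(p, grid).values.real, expected)

    def test_wrong_coefficient_length_raises(self, grid):
        p = BaselineParams(np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError):
            baseline_forward(p, grid)

    def test_baseline_has_no_detail_band_energy(self, grid):
        model = WaveletBaselineModel(grid.n_points)
        rng = np.random.default_rng(9)
        signal = model.reconstruct(rng.normal(size=model.n_coeffs))
        dec = pywt.wavedec(signal, model.wavelet, mode="periodization",
                           level=model.level)
        for detail in dec[1:]:
            assert np.max(np.abs(detail)) < 1e-10


class TestModelForward:
    def test_zero_baseline_equals_metabolite_model(self, basis, params, zero_baseline):
        total = model_forward(basis, params, zero_baseline).values
        metab = metabolite_forward(basis, params).values
        assert np.allclose(total, metab)

    def test_zero_amplitudes_equal_baseline(self, grid, basis):
        rng = np.random.default_rng(2)
        bp = BaselineParams(rng.normal(size=N_COEFFS),
                            rng.normal(size=N_COEFFS))
        p = MetabParams(np.zeros(3))
        total = model_forward(basis, p, bp).values
        assert np.allclose(total, baseline_forward(bp, grid).values)

    def test_both_zero_gives_zero(self, basis, zero_baseline):
        p = MetabParams(np.zeros(3))
        assert np.allclose(model_forward(basis, p, zero_baseline).values, 0.0)

    def test_spectrum_rejects_nonfinite(self, grid):
        values = np.zeros(grid.n_points, dtype=complex)
        values[3] = np.nan
        with pytest.raises(ValueError):
            Spectrum(values, grid)
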