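import numpy as np
import pytest
from scipy.signal.windows import hann

from quspred.containers import RFFrame, ROIMask
from quspred.roi import AnalysisBlock, tile_blocks
from quspred.spectral import (
    NormalizedSpectrum,
    attenuation_db,
    block_power_spectrum,
    correct_attenuation,
    estimate_ace,
    fit_linear_spectrum,
    normalize_spectrum,
)
from quspred.simulate import synthesize_block_spectrum


def line_spectrum(slope, intercept, band=(3.0, 8.0), n=51):
    f = np.linspace(band[0], band[1], n)
    return NormalizedSpectrum(f, slope * f + intercept, band)


class TestLinearFit:
    def test_exact_line_recovers_ss_si_mbf(self):
        fit = fit_linear_spectrum(line_spectrum(2.0, 3.0))
        assert fit.ss_db_mhz == pytest.approx(2.0, abs=1e-9)
        assert fit.si_db == pytest.approx(3.0, abs=1e-9)
        assert fit.mbf_db == pytest.approx(2.0 * 5.5 + 3.0, abs=1e-9)

    def test_constant_spectrum(self):
        fit = fit_linear_spectrum(line_spectrum(0.0, -7.5))
        assert fit.ss_db_mhz == pytest.approx(0.0, abs=1e-9)
        assert fit.si_db == pytest.approx(-7.5, abs=1e-9)
        assert fit.mbf_db == pytest.approx(-7.5, abs=1e-9)

    def test_mbf_identity_holds(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            f = np.linspace(3, 8, 40)
            spec = NormalizedSpectrum(f, rng.normal(size=40), (3.0, 8.0))
            fit = fit_linear_spectrum(spec)
            assert fit.mbf_db == pytest.approx(fit.ss_db_mhz * 5.5 + fit.si_db, abs=1e-9)

    def test_slope_estimator_unbiased(self):
        rng = np.random.default_rng(5)
        slopes = []
        for _ in range(1000):
            f = np.linspace(3, 8, 26)
            spec = NormalizedSpectrum(f, 2.0 * f + 3.0 + rng.normal(0, 1, 26), (3.0, 8.0))
            slopes.append(fit_linear_spectrum(spec).ss_db_mhz)
        # CLT band for the mean of 1000 regression slopes
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 2.0) < 3 * se

    def test_degenerate_band_rejected(self):
        f = np.array([5.0, 5.0])
        spec = NormalizedSpectrum(f, np.array([1.0, 2.0]), (5.0, 5.0 + 1e-12))
        with pytest.raises(ValueError):
            fit_linear_spectrum(spec)


class TestBlockSpectrum:
    def _tone_frame(self, f0=6e6, n=2048, lines=8):
        t = np.arange(n) / 40e6
        rf = np.sin(2 * np.pi * f0 * t)[:, None] * np.ones((1, lines))
        return RFFrame(rf, 40e6, 0.3)

    def test_tone_peaks_at_carrier(self):
        frame = self._tone_frame()
        block = AnalysisBlock(200, 0, 512, 8, 0.0)
        f, p = block_power_spectrum(frame, block)
        assert f[int(np.argmax(p))] == pytest.approx(6.0, abs=40 / 512)

    def test_parseval_identity(self):
        rng = np.random.default_rng(1)
        frame = RFFrame(rng.normal(size=(512, 4)), 40e6, 0.3)
        block = AnalysisBlock(64, 0, 256, 4, 0.0)
        f, p = block_power_spectrum(frame, block)
        w = hann(256, sym=False)
        seg = frame.samples[64:320, :] * w[:, None]
        # rfft bins double-count all but DC/Nyquist
        weights = np.full(p.size, 2.0)
        weights[0] = 1.0
        if 256 % 2 == 0:
            weights[-1] = 1.0
        lhs = np.sum(p * weights) / 256
        rhs = np.mean(np.sum(seg**2, axis=0)) / np.sum(w**2)
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_white_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(2)
        frame = RFFrame(rng.normal(size=(4096, 64)), 40e6, 0.3)
        acc = None
        for r0 in range(0, 3840, 128):
            block = AnalysisBlock(r0, 0, 256, 64, 0.0)
            f, p = block_power_spectrum(frame, block)
            acc = p if acc is None else acc + p
        db = 10 * np.log10(acc[2:-2])
        assert np.ptp(db) < 1.0

    def test_block_outside_frame_rejected(self):
        frame = self._tone_frame()
        with pytest.raises(ValueError):
            block_power_spectrum(frame, AnalysisBlock(1900, 0, 512, 8, 0.0))


class TestNormalization:
    def test_identity_gives_zero_db(self):
        f = np.linspace(0, 20, 101)
        p = np.exp(-((f - 6) ** 2))
        spec = normalize_spectrum(p, p, f)
        np.testing.assert_allclose(spec.power_db[spec.band_mask], 0.0, atol=1e-12)

    def test_factor_four_gives_6dB(self):
        f = np.linspace(0, 20, 101)
        p = np.exp(-((f - 6) ** 2)) + 0.1
        spec = normalize_spectrum(4 * p, p, f)
        np.testing.assert_allclose(
            spec.power_db[spec.band_mask], 10 * np.log10(4), atol=1e-12
        )

    def test_zero_reference_in_band_rejected(self):
        f = np.linspace(0, 20, 101)
        ref = np.ones(101)
        ref[30] = 0.0  # inside 3-8 MHz
        with pytest.raises(ZeroDivisionError):
            normalize_spectrum(np.ones(101), ref, f)


class TestAttenuationCorrection:
    def test_no_excess_attenuation_is_identity(self):
        spec = synthesize_block_spectrum(25, 0)
        out = correct_attenuation(spec, 0.5, 0.5, path_cm=2.0)
        np.testing.assert_array_equal(out.power_db, spec.power_db)

    def test_correct_inverts_apply(self):
        spec = synthesize_block_spectrum(25, 0)
        attenuated = NormalizedSpectrum(
            spec.freq_mhz,
            spec.power_db - attenuation_db(0.6, spec.freq_mhz, 2.5),
            spec.band_mhz,
        )
        restored = correct_attenuation(attenuated, 0.5 + 0.6, 0.5, path_cm=2.5)
        np.testing.assert_allclose(restored.power_db, spec.power_db, atol=1e-10)

    def test_negative_path_rejected(self):
        spec = synthesize_block_spectrum(25, 0)
        with pytest.raises(ValueError):
            correct_attenuation(spec, 1.0, 0.5, path_cm=-1.0)


class TestACE:
    def test_sample_equal_to_reference_recovers_reference_alpha(self, frame_pair):
        _, ref = frame_pair
        core = ROIMask(np.ones(ref.samples.shape, bool), "core")
        est = estimate_ace(ref, core, ref, alpha_reference_db_cm_mhz=0.5)
        # sample blocks tile a lattice while the reference divisor averages
        # the full aperture, so cancellation is near- but not bit-exact
        assert est.ace_db_cm_mhz == pytest.approx(0.5, abs=0.01)
        assert est.residual_db < 0.05

    def test_recovers_excess_attenuation(self, frame_pair, core_mask):
        sam, ref = frame_pair  # alpha = 1.0 vs reference 0.5
        est = estimate_ace(sam, core_mask, ref, alpha_reference_db_cm_mhz=0.5)
        assert est.ace_db_cm_mhz == pytest.approx(1.0, rel=0.15)

    def test_insufficient_depth_span_rejected(self, frame_pair):
        sam, ref = frame_pair
        shallow = np.zeros(sam.samples.shape, bool)
        shallow[800:950, :] = True  # < 10 mm axial span
        with pytest.raises(ValueError, match="span"):
            estimate_ace(sam, ROIMask(shallow, "core"), ref, 0.5)


class TestCrossFidelity:
    def test_rf_route_matches_spectrum_oracle_within_3db(self, pulse):
        """Mean normalized+corrected spectrum from simulated RF equals the
        backscatter-model ratio of the spectrum-level oracle."""
        from quspred.backscatter import backscatter_model_db
        from quspred.simulate import make_scatterer_phantom, simulate_rf_frame

        n_lines, pitch, depth = 48, 0.3, 30.0
        n_samples = int(np.ceil(2 * depth * 1e-3 / 1540 * 40e6)) + 96
        a_s, aac_s, al_s = 25.0, 2.0, 1.0
        a_r, aac_r, al_r = 5.0, 0.0, 0.5
        ref = simulate_rf_frame(
            make_scatterer_phantom(depth, n_lines * pitch, 60, a_r, aac_r, al_r, seed=9),
            pulse, n_lines, pitch, n_samples=n_samples,
        )
        sam = simulate_rf_frame(
            make_scatterer_phantom(depth, n_lines * pitch, 60, a_s, aac_s, al_s, seed=1),
            pulse, n_lines, pitch, n_samples=n_samples,
        )
        mask = ROIMask(np.ones((n_samples, n_lines), bool), "core")
        blocks = tile_blocks(mask, sam, min_inside=1.0)
        acc = 0.0
        for b in blocks:
            f, ps = block_power_spectrum(sam, b)
            _, pr = block_power_spectrum(ref, b)
            spec = normalize_spectrum(ps, pr, f, depth_mm=b.depth_mm, path_mm=b.depth_mm)
            acc = acc + correct_attenuation(spec, al_s, al_r).power_db
        mean_db = acc / len(blocks)
        band = (f >= 3) & (f <= 8)
        oracle = backscatter_model_db(f[band], a_s, aac_s) - backscatter_model_db(
            f[band], a_r, aac_r
        )
        assert np.abs(mean_db[band] - oracle).max() < 3.0
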