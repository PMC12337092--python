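"""CH-stretch band metrics: normalization, apex position, width, order ratio."""

import numpy as np
import pytest

from memphys import spectra, synthetic
from memphys.exceptions import DomainError
from memphys.spectra import (FTIR_NU_AS_CH2_WINDOW, Spectrum, band_fwhm,
                             normalize, peak_position, pseudo_voigt,
                             raman_order_ratio)

WIDE_WINDOW = (2845.0, 3005.0)


class TestNormalize:
    def test_anchor_apex_becomes_one(self, raman_clean):
        out = normalize(raman_clean, 2850.0)
        nu, y = out.window(2835.0, 2865.0)
        from memphys._peaks import quadratic_apex_fit
        _, h = quadratic_apex_fit(nu, y)
        assert h == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self, raman_clean):
        once = normalize(raman_clean, 2850.0)
        twice = normalize(once, 2850.0)
        assert np.array_equal(once.intensity, twice.intensity)

    def test_band_height_ratio_preserved(self, raman_clean):
        before = raman_order_ratio(raman_clean)
        after = raman_order_ratio(normalize(raman_clean, 2850.0))
        assert after == pytest.approx(before, rel=1e-12)

    def test_nonpositive_anchor_rejected(self):
        nu = np.arange(2750.0, 3052.0, 4.0)
        sp = Spectrum(nu, np.zeros_like(nu) - 1.0)
        with pytest.raises(DomainError):
            normalize(sp, 2850.0)


class TestPeakPosition:
    def test_symmetric_band_apex_at_center(self, ftir_clean):
        pos = peak_position(ftir_clean, FTIR_NU_AS_CH2_WINDOW)
        assert pos == pytest.approx(ftir_clean.meta["apex_true_1"], abs=0.1)

    def test_shift_between_band_pair_recovered(self, ftir_clean):
        shifted = synthetic.gen_spectrum(synthetic.SpectrumConfig(
            seed=0, bands=((2853.0, 0.75, 20.0), (2925.0, 1.0, 28.0)),
            snr=float("inf")))
        shift = (peak_position(shifted, FTIR_NU_AS_CH2_WINDOW)
                 - peak_position(ftir_clean, FTIR_NU_AS_CH2_WINDOW))
        truth = shifted.meta["apex_true_1"] - ftir_clean.meta["apex_true_1"]
        assert shift == pytest.approx(truth, abs=0.1)

    def test_flat_spectrum_rejected(self):
        nu = np.arange(2750.0, 3052.0, 4.0)
        sp = Spectrum(nu, np.ones_like(nu))
        with pytest.raises(DomainError):
            peak_position(sp, FTIR_NU_AS_CH2_WINDOW)

    def test_offset_removal_leaves_position(self, ftir_clean):
        # apex position is invariant when a constant offset is removed
        p1 = peak_position(ftir_clean, FTIR_NU_AS_CH2_WINDOW)
        lifted = ftir_clean.replace_intensity(ftir_clean.intensity + 0.2)
        p2 = peak_position(lifted.replace_intensity(lifted.intensity - 0.2),
                           FTIR_NU_AS_CH2_WINDOW)
        assert p2 == pytest.approx(p1, abs=1e-12)

    def test_center_of_gravity_option(self, ftir_clean):
        pos = peak_position(ftir_clean, FTIR_NU_AS_CH2_WINDOW, method="cog")
        assert pos == pytest.approx(2923.1, abs=1.5)

    def test_grid_refinement_stability(self):
        coarse = synthetic.gen_spectrum(synthetic.SpectrumConfig(
            seed=0, snr=float("inf"), step_cm1=4.0))
        fine = synthetic.gen_spectrum(synthetic.SpectrumConfig(
            seed=0, snr=float("inf"), step_cm1=2.0))
        p_c = peak_position(coarse, FTIR_NU_AS_CH2_WINDOW)
        p_f = peak_position(fine, FTIR_NU_AS_CH2_WINDOW)
        assert abs(p_c - p_f) <= 4.0  # within one coarse grid step

    def test_position_repeatability_at_snr_100(self):
        positions = [
            peak_position(synthetic.gen_spectrum(
                synthetic.SpectrumConfig(seed=s)), FTIR_NU_AS_CH2_WINDOW)
            for s in range(20)]
        assert np.std(positions) < 0.2


class TestBandFwhm:
    def test_lorentzian_closed_form(self):
        # pure Lorentzian of half-width gamma=8: fwhm = 16
        sp = synthetic.gen_spectrum(synthetic.SpectrumConfig(
            seed=0, bands=((2900.0, 1.0, 16.0),), eta=1.0,
            snr=float("inf"), step_cm1=1.0))
        w = band_fwhm(sp, (2760.0, 3040.0))
        assert w == pytest.approx(16.0, rel=5e-3)

    def test_isolated_band_generator_width_recovered(self):
        sp = synthetic.gen_spectrum(synthetic.SpectrumConfig(
            seed=0, bands=((2923.1, 1.0, 24.1),), snr=float("inf")))
        assert band_fwhm(sp, WIDE_WINDOW) == pytest.approx(24.1, abs=0.2)

    def test_intensity_scaling_invariance(self, ftir_clean):
        w1 = band_fwhm(ftir_clean, (2890.0, 2960.0))
        w2 = band_fwhm(ftir_clean.replace_intensity(
            ftir_clean.intensity * 11.0), (2890.0, 2960.0))
        assert w2 == pytest.approx(w1, rel=1e-12)

    def test_ambiguous_bimodal_window_rejected(self, raman_clean):
        from memphys.exceptions import AmbiguousPeakError
        with pytest.raises((AmbiguousPeakError, DomainError)):
            band_fwhm(raman_clean, (2770.0, 3040.0), baseline="none")


class TestRamanOrderRatio:
    def test_composite_truth_recovered_noise_free(self, raman_clean):
        truth = (raman_clean.meta["apex_height_true_2"]
                 / raman_clean.meta["apex_height_true_0"])
        assert raman_order_ratio(raman_clean) == pytest.approx(truth, rel=0.01)

    def test_identical_bands_give_unity(self):
        sp = synthetic.gen_spectrum(synthetic.SpectrumConfig(
            seed=0, kind="Raman",
            bands=((2850.0, 1.0, 16.0), (2930.0, 1.0, 16.0)),
            snr=float("inf")))
        assert raman_order_ratio(sp) == pytest.approx(1.0, abs=1e-6)

    def test_global_scaling_invariance(self, raman_clean):
        r1 = raman_order_ratio(raman_clean)
        r2 = raman_order_ratio(raman_clean.replace_intensity(
            raman_clean.intensity * 0.37))
        assert r2 == pytest.approx(r1, rel=1e-12)

    def test_missing_band_rejected(self):
        sp = synthetic.gen_spectrum(synthetic.SpectrumConfig(
            seed=0, kind="Raman", bands=((2850.0, 1.0, 14.0),),
            snr=float("inf")))
        with pytest.raises(DomainError):
            raman_order_ratio(sp)


def test_pseudo_voigt_apex_height_and_halfwidth():
    nu = np.linspace(2800, 3000, 20001)
    y = pseudo_voigt(nu, 2900.0, 0.8, 24.0, eta=0.3)
    assert y.max() == pytest.approx(0.8, rel=1e-6)
    above = nu[y >= 0.4]
    assert above[-1] - above[0] == pytest.approx(24.0, abs=0.05)
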