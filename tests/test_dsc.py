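"""DSC thermogram analysis: baseline, Tm, enthalpy, width, deconvolution."""

import math

import numpy as np
import pytest

from memphys import dsc, synthetic
from memphys.dsc import (Thermogram, deconvolve_two, find_tm, fwhm,
                         gaussian_peak, integrate_dh, subtract_baseline)
from memphys.exceptions import AmbiguousPeakError, DomainError

FLANKS = ((-40.0, -30.0), (-5.0, 0.0))


def _grid(step=0.05):
    return np.arange(-40.0, 0.0 + step / 2, step)


class TestBaseline:
    def test_flat_input_unchanged(self, control_thermogram_clean):
        out = subtract_baseline(control_thermogram_clean, FLANKS)
        assert np.max(np.abs(out.cp_excess
                             - control_thermogram_clean.cp_excess)) < 1e-12

    def test_known_linear_drift_removed(self):
        T = _grid()
        drift = 0.05 + 0.002 * T
        peak = gaussian_peak(T, 9.18, -16.72, 2.27)
        tg = Thermogram(T, peak + drift)
        out = subtract_baseline(tg, FLANKS)
        truth_area = 9.18  # analytic Gaussian area
        assert integrate_dh(out) == pytest.approx(truth_area, rel=5e-3)

    def test_window_over_apex_rejected(self, control_thermogram_clean):
        with pytest.raises(DomainError):
            subtract_baseline(control_thermogram_clean,
                              ((-20.0, -14.0), (-5.0, 0.0)))


class TestFindTm:
    def test_symmetric_peak_apex_is_center(self, control_thermogram_clean):
        flat = subtract_baseline(control_thermogram_clean, FLANKS)
        assert find_tm(flat) == pytest.approx(-16.72, abs=1e-3)

    def test_grid_offset_peak_located_subgrid(self):
        T = _grid(0.05)
        center = -16.7213  # deliberately between samples
        tg = Thermogram(T, gaussian_peak(T, 9.18, center, 2.27))
        assert find_tm(tg) == pytest.approx(center, abs=0.02)

    def test_monotone_ramp_rejected(self):
        T = _grid(0.5)
        with pytest.raises(DomainError):
            find_tm(Thermogram(T, np.linspace(0, 1, len(T))))


class TestIntegrateDh:
    def test_zero_curve_integrates_to_zero(self):
        T = _grid(0.5)
        assert integrate_dh(Thermogram(T, np.zeros_like(T))) == 0.0

    def test_gaussian_analytic_area(self):
        # area parameterization: height * sigma * sqrt(2 pi) == 9.18
        T = _grid()
        tg = Thermogram(T, gaussian_peak(T, 9.18, -16.72, 2.27))
        assert integrate_dh(tg) == pytest.approx(9.18, rel=1e-3)

    def test_two_disjoint_peaks_areas_add(self):
        T = _grid()
        a, b = 4.1, 2.7
        tg = Thermogram(T, gaussian_peak(T, a, -25.0, 1.5)
                        + gaussian_peak(T, b, -12.0, 1.5))
        assert integrate_dh(tg) == pytest.approx(a + b, rel=1e-3)


class TestFwhm:
    def test_gaussian_closed_form(self):
        # fwhm = 2.3548 sigma; sigma = 0.964 C -> 2.27 C
        sigma = 0.964
        T = _grid()
        tg = Thermogram(T, gaussian_peak(T, 5.0, -16.72,
                                         sigma * dsc.GAUSS_FWHM_FACTOR))
        assert fwhm(tg) == pytest.approx(2.27, rel=5e-3)

    def test_intensity_scaling_leaves_width_unchanged(
            self, control_thermogram_clean):
        w1 = fwhm(control_thermogram_clean)
        w2 = fwhm(control_thermogram_clean.replace_cp(
            control_thermogram_clean.cp_excess * 7.3))
        assert w2 == pytest.approx(w1, rel=1e-12)

    def test_bimodal_curve_raises_ambiguity(self):
        T = _grid()
        tg = Thermogram(T, gaussian_peak(T, 3.0, -25.0, 1.5)
                        + gaussian_peak(T, 3.0, -12.0, 1.5))
        with pytest.raises(AmbiguousPeakError):
            fwhm(tg)


class TestHeatflowConversion:
    def test_known_conversion(self):
        # 1 mW at 5 C/min over 1e-6 mol: 1e-3 J/s / (1/12 C/s * 1e-6 mol)
        # = 12000 J/mol/C = 2.868 kcal/mol/C
        T = _grid(0.5)
        hf = np.ones_like(T)
        tg = Thermogram.from_heatflow(T, hf, 5.0, 1e-6)
        assert tg.cp_excess[0] == pytest.approx(12000.0 / 4184.0, rel=1e-12)

    def test_exotherm_sign_flipped_to_positive(self):
        T = _grid(0.5)
        hf = -gaussian_peak(T, 5.0, -16.72, 2.0)
        tg = Thermogram.from_heatflow(T, hf, 5.0, 1e-6)
        assert tg.cp_excess.max() > 0
        assert abs(tg.cp_excess.min()) < tg.cp_excess.max()


class TestDeconvolveTwo:
    TRUTH = synthetic.CONTROL_TWO_COMPONENT_TRUTH

    def test_noise_free_recovery_to_four_significant_figures(self):
        tg = synthetic.gen_thermogram(synthetic.ThermogramConfig(
            seed=0, components=self.TRUTH, snr=float("inf"), drift=(0.0,)))
        fit = deconvolve_two(tg)
        assert not fit.fallback_single
        (tm1, a1, w1), (tm2, a2, w2) = self.TRUTH
        c1, c2 = fit.components
        assert c1.tm_c == pytest.approx(tm1, rel=1e-4)
        assert c2.tm_c == pytest.approx(tm2, rel=1e-4)
        assert c1.area_kcal_mol == pytest.approx(a1, rel=1e-4)
        assert c2.area_kcal_mol == pytest.approx(a2, rel=1e-4)
        assert c1.fwhm_c == pytest.approx(w1, rel=1e-4)
        assert c2.fwhm_c == pytest.approx(w2, rel=1e-4)

    def test_fractions_sum_to_100(self):
        tg = synthetic.gen_thermogram(synthetic.ThermogramConfig(
            seed=3, components=self.TRUTH, snr=50))
        fit = deconvolve_two(subtract_baseline(tg, FLANKS))
        assert sum(c.fraction_pct for c in fit.components) == pytest.approx(
            100.0, abs=0.1)

    def test_component_areas_match_model_integral(self):
        tg = synthetic.gen_thermogram(synthetic.ThermogramConfig(
            seed=4, components=self.TRUTH, snr=50))
        fit = deconvolve_two(subtract_baseline(tg, FLANKS))
        T = tg.T_c
        model_area = np.trapezoid(fit.model_curve(T), T)
        assert model_area == pytest.approx(
            sum(c.area_kcal_mol for c in fit.components), rel=1e-3)

    def test_single_gaussian_input_falls_back_flagged(
            self, control_thermogram_clean):
        fit = deconvolve_two(control_thermogram_clean)
        assert fit.fallback_single and len(fit.components) == 1

    def test_init_label_order_irrelevant(self):
        tg = synthetic.gen_thermogram(synthetic.ThermogramConfig(
            seed=5, components=self.TRUTH, snr=float("inf"), drift=(0.0,)))
        fit_a = deconvolve_two(tg, init=list(self.TRUTH))
        fit_b = deconvolve_two(tg, init=list(reversed(self.TRUTH)))
        for ca, cb in zip(fit_a.components, fit_b.components):
            assert ca.tm_c == pytest.approx(cb.tm_c, abs=1e-6)
            assert ca.fraction_pct == pytest.approx(cb.fraction_pct, abs=1e-4)

    def test_components_sorted_higher_tm_first(self):
        tg = synthetic.gen_thermogram(synthetic.ThermogramConfig(
            seed=6, components=self.TRUTH, snr=50))
        fit = deconvolve_two(subtract_baseline(tg, FLANKS))
        assert fit.components[0].tm_c > fit.components[1].tm_c

    def test_scale_equivariance_of_areas(self):
        tg = synthetic.gen_thermogram(synthetic.ThermogramConfig(
            seed=7, components=self.TRUTH, snr=float("inf"), drift=(0.0,)))
        fit1 = deconvolve_two(tg)
        fit2 = deconvolve_two(tg.replace_cp(tg.cp_excess * 3.0))
        assert fit2.total_dh_kcal_mol == pytest.approx(
            3.0 * fit1.total_dh_kcal_mol, rel=1e-6)
        assert fit2.components[0].tm_c == pytest.approx(
            fit1.components[0].tm_c, abs=1e-6)
        assert fit2.components[0].fwhm_c == pytest.approx(
            fit1.components[0].fwhm_c, rel=1e-6)


class TestEmgLineshape:
    def test_area_normalization(self):
        T = _grid()
        y = dsc.emg_peak(T, 6.0, -20.0, 2.0, 1.5)
        assert np.trapezoid(y, T) == pytest.approx(6.0, rel=1e-3)
        assert np.all(np.isfinite(y))

    def test_single_skewed_component_recovered(self):
        T = _grid()
        tg = Thermogram(T, dsc.emg_peak(T, 6.0, -20.0, 2.0, 1.5))
        fit = deconvolve_two(tg, lineshape="emg")
        assert fit.fallback_single
        c = fit.components[0]
        assert c.tm_c == pytest.approx(-20.0, abs=1e-6)
        assert c.area_kcal_mol == pytest.approx(6.0, rel=1e-6)
        assert c.tau_c == pytest.approx(1.5, rel=1e-6)
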