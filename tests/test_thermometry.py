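"""Unmixing, calibration, inversion and profile fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irlego import synthetic as syn
from irlego import thermometry as th


def grid_search_unmix(spectrum, basis, step=0.001, upper=1.0):
    """Exhaustive SSE minimization over (a_fitc, a_tamra) in [0, upper]^2.

    Independent of the NNLS route: evaluates the quadratic SSE surface on a
    dense coefficient grid via its Gram expansion.
    """
    y = np.interp(basis.grid, spectrum.wavelengths, spectrum.intensities)
    f = basis.fitc_basis.intensities
    t = basis.tamra_basis.intensities
    a = np.arange(0.0, upper + step / 2, step)
    ff, tt, ft = f @ f, t @ t, f @ t
    yf, yt = y @ f, y @ t
    sse = (
        (a**2 * ff)[:, None]
        + (a**2 * tt)[None, :]
        + 2 * np.outer(a, a) * ft
        - 2 * (a * yf)[:, None]
        - 2 * (a * yt)[None, :]
    )
    i, j = np.unravel_index(np.argmin(sse), sse.shape)
    return a[i], a[j]


class TestUnmix:
    def test_pure_basis_identity(self, default_basis):
        res = th.unmix_spectrum(default_basis.tamra_basis, default_basis)
        assert res.a_fitc == pytest.approx(0.0, abs=1e-12)
        assert res.a_tamra == pytest.approx(1.0, rel=1e-9)
        assert res.residual_rms == pytest.approx(0.0, abs=1e-12)

    def test_noisy_mixture_matches_grid_search_oracle(self, default_basis):
        cfg = syn.SpectraGenConfig(noise_cv=0.01, seed=3)
        spec = syn.generate_mixture_spectrum(0.3, 0.7, cfg.ref_temperature, cfg)
        res = th.unmix_spectrum(spec, default_basis)
        a_f, a_t = grid_search_unmix(spec, default_basis)
        assert res.a_fitc == pytest.approx(a_f, abs=2e-3)
        assert res.a_tamra == pytest.approx(a_t, abs=2e-3)
        assert abs(res.a_fitc - 0.3) < 0.02 and abs(res.a_tamra - 0.7) < 0.02

    def test_all_zero_spectrum_flagged(self, default_basis):
        zero = th.EmissionSpectrum(default_basis.grid, np.zeros(default_basis.grid.size))
        res = th.unmix_spectrum(zero, default_basis)
        assert (res.a_fitc, res.a_tamra) == (0.0, 0.0)
        assert not res.ratio_defined
        assert np.isnan(res.ratio)

    def test_insufficient_overlap_rejected(self, default_basis):
        wl = np.linspace(470.0, 500.0, 31)
        spec = th.EmissionSpectrum(wl, np.ones(31))
        with pytest.raises(ValueError, match="80%"):
            th.unmix_spectrum(spec, default_basis)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(k=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_equivariance_and_ratio_invariance(self, k, default_basis):
        """Scaling the spectrum scales the coefficients and leaves the ratio
        unchanged — the excitation-power immunity of the dual-dye read-out."""
        cfg = syn.SpectraGenConfig(noise_cv=0.0)
        spec = syn.generate_mixture_spectrum(0.4, 0.6, 30.0, cfg)
        scaled = th.EmissionSpectrum(spec.wavelengths, k * spec.intensities)
        base = th.unmix_spectrum(spec, default_basis)
        res = th.unmix_spectrum(scaled, default_basis)
        assert res.a_fitc == pytest.approx(k * base.a_fitc, rel=1e-6)
        assert res.a_tamra == pytest.approx(k * base.a_tamra, rel=1e-6)
        assert res.ratio == pytest.approx(base.ratio, rel=1e-9)


class TestRatioCalibration:
    def test_exact_line_through_collinear_points(self):
        cal = th.fit_ratio_calibration([(25.0, 1.00), (30.0, 0.90), (35.0, 0.80)])
        assert cal.slope == pytest.approx(-0.02, abs=1e-12)
        assert cal.intercept == pytest.approx(1.50, abs=1e-12)
        assert cal.r_squared == pytest.approx(1.0)

    def test_relative_slope_recovers_dye_sensitivity_difference(
        self, calibration_noiseless
    ):
        """The fitted fractional ratio slope equals s_TAMRA − s_FITC =
        −0.717 %/°C to first order; the exact value over the 25–38 °C ramp
        referenced to 23 °C is (s_T−s_F)/(1+s_F·ΔT_mid)² = −0.7376 %/°C
        (ratio-curvature correction, derived in closed form)."""
        rel = 100.0 * calibration_noiseless.relative_sensitivity
        assert rel == pytest.approx(-0.7376, abs=0.003)
        assert rel == pytest.approx(-0.717, abs=0.025)

    def test_single_temperature_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            th.fit_ratio_calibration([(25.0, 1.0), (25.0, 1.01)])

    def test_positive_slope_warns(self):
        with pytest.warns(UserWarning, match="not negative"):
            th.fit_ratio_calibration([(25.0, 0.8), (30.0, 0.9), (35.0, 1.0)])

    def test_unknown_medium_rejected(self):
        with pytest.raises(ValueError, match="medium"):
            th.fit_ratio_calibration([(25.0, 1.0), (30.0, 0.9)], medium="vacuum")


class TestInversion:
    def test_known_calibration_inverts(self):
        cal = th.RatioCalibration(-0.02, 1.50, 23.0, "water", 1.0, 0.0, 3)
        assert th.ratio_to_temperature(0.90, cal) == pytest.approx(30.0)
        assert th.ratio_to_temperature(cal.predicted_ratio(25.0), cal) == pytest.approx(25.0)

    def test_zero_slope_rejected(self):
        cal = th.RatioCalibration(0.0, 1.0, 23.0, "water", 0.0, 0.0, 2)
        with pytest.raises(ZeroDivisionError):
            th.ratio_to_temperature(0.9, cal)

    def test_round_trip_identity_on_noiseless_data(
        self, noiseless_cfg, default_basis, calibration_noiseless
    ):
        """Calibrate → invert reproduces the true temperature to < 0.05 degC
        over the calibrated range."""
        for t_true in np.arange(25.0, 38.5, 1.0):
            spec = syn.generate_mixture_spectrum(1.0, 1.0, t_true, noiseless_cfg)
            ratio = th.unmix_spectrum(spec, default_basis).ratio
            t_meas = th.ratio_to_temperature(ratio, calibration_noiseless)
            assert abs(t_meas - t_true) < 0.05

    def test_measured_vs_true_slope_near_unity(self, default_basis):
        """End-to-end validation: regression of thermometry-measured on true
        temperature has slope in [0.97, 1.03]."""
        cal_cfg = syn.SpectraGenConfig(noise_cv=0.01, seed=21)
        val_cfg = syn.SpectraGenConfig(noise_cv=0.01, seed=22)
        temps = np.arange(25.0, 38.5, 1.0)
        series = syn.generate_calibration_series(temps, 5, cal_cfg)
        cal = th.fit_ratio_calibration(
            [(t, th.unmix_spectrum(s, default_basis)) for t, s in series]
        )
        validation = syn.generate_calibration_series(temps, 5, val_cfg)
        true_t, meas_t = [], []
        for t, s in validation:
            ratio = th.unmix_spectrum(s, default_basis).ratio
            true_t.append(t)
            meas_t.append(th.ratio_to_temperature(ratio, cal))
        slope = np.polyfit(true_t, meas_t, 1)[0]
        assert 0.97 <= slope <= 1.03


class TestTemperatureRise:
    def test_identical_spectra_give_zero(self, noiseless_cfg, default_basis):
        spec = syn.generate_mixture_spectrum(1.0, 1.0, 23.0, noiseless_cfg)
        dt = th.temperature_rise_from_spectra(spec, spec, default_basis, -0.00717)
        assert dt == pytest.approx(0.0, abs=1e-12)

    def test_ten_degree_rise_recovered(self, noiseless_cfg, default_basis):
        before = syn.generate_mixture_spectrum(1.0, 1.0, 23.0, noiseless_cfg)
        after = syn.generate_mixture_spectrum(1.0, 1.0, 33.0, noiseless_cfg)
        dt = th.temperature_rise_from_spectra(
            before, after, default_basis,
            noiseless_cfg.sens_tamra - noiseless_cfg.sens_fitc,
        )
        assert dt == pytest.approx(10.0, abs=0.2)

    def test_exact_inversion_is_exact(self, noiseless_cfg, default_basis):
        before = syn.generate_mixture_spectrum(1.0, 1.0, 25.0, noiseless_cfg)
        after = syn.generate_mixture_spectrum(1.0, 1.0, 36.0, noiseless_cfg)
        dt = th.temperature_rise_from_spectra(
            before, after, default_basis, -0.00717,
            exact=True,
            sens_fitc=noiseless_cfg.sens_fitc,
            sens_tamra=noiseless_cfg.sens_tamra,
            t_before=25.0,
            ref_temperature=noiseless_cfg.ref_temperature,
        )
        assert dt == pytest.approx(11.0, abs=1e-9)

    def test_cooling_sign_convention(self, noiseless_cfg, default_basis):
        # ratio going UP with a negative sensitivity means cooling
        before = syn.generate_mixture_spectrum(1.0, 1.0, 33.0, noiseless_cfg)
        after = syn.generate_mixture_spectrum(1.0, 1.0, 23.0, noiseless_cfg)
        dt = th.temperature_rise_from_spectra(before, after, default_basis, -0.00717)
        assert dt < 0


class TestDyeSensitivity:
    def test_recovers_generator_sensitivity(self, default_basis):
        cfg = syn.SpectraGenConfig(noise_cv=0.01, seed=31)
        temps = np.arange(25.0, 61.0, 5.0)
        series = syn.generate_calibration_series(temps, 3, cfg, a_fitc=0.0, a_tamra=1.0)
        t = np.array([x for x, _ in series])
        intens = np.array([s.area for _, s in series])
        fit = th.fit_dye_sensitivity(t, intens, cfg.ref_temperature)
        assert abs(fit.sensitivity - cfg.sens_tamra) < 3 * fit.stderr + 1e-5


class TestProfiles:
    def test_ambient_plus_rise(self):
        prof = th.assemble_profile([(0.0, 27.0)], ambient=23.0)
        assert prof.temperature[0] == pytest.approx(50.0)

    def test_replicates_aggregate_to_mean_sd(self):
        prof = th.assemble_profile([(10.0, 4.0), (10.0, 6.0)], ambient=23.0)
        assert prof.temperature[0] == pytest.approx(28.0)
        assert prof.sd[0] == pytest.approx(np.sqrt(2.0), abs=1e-9)

    def test_positions_sorted(self):
        prof = th.assemble_profile([(5.0, 1.0), (-5.0, 2.0), (0.0, 3.0)])
        np.testing.assert_array_equal(prof.positions, [-5.0, 0.0, 5.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            th.assemble_profile([])


class TestTwoTermGaussian:
    @staticmethod
    def _curve(x, a1, c1, w1, a2, c2, w2, off):
        return (
            off
            + a1 * np.exp(-(((x - c1) / w1) ** 2))
            + a2 * np.exp(-(((x - c2) / w2) ** 2))
        )

    def test_round_trip_on_exact_curve(self):
        x = np.linspace(-30.0, 30.0, 41)
        truth = (20.0, -3.0, 6.0, 8.0, 4.0, 12.0, 23.0)
        prof = th.TemperatureProfile(x, self._curve(x, *truth))
        fit = th.fit_two_term_gaussian(prof)
        # parameters recovered up to permutation of the two terms
        got = sorted(zip(fit.amplitudes, fit.centers, fit.widths))
        want = sorted([(20.0, -3.0, 6.0), (8.0, 4.0, 12.0)])
        for (ga, gc, gw), (wa, wc, ww) in zip(got, want):
            assert ga == pytest.approx(wa, rel=1e-4)
            assert gc == pytest.approx(wc, abs=1e-3)
            assert gw == pytest.approx(ww, rel=1e-4)
        assert fit.offset == pytest.approx(23.0, rel=1e-4)
        assert fit.rms_residual < 1e-6

    def test_single_gaussian_limit_judged_on_residual(self):
        x = np.linspace(-20.0, 20.0, 31)
        y = 23.0 + 15.0 * np.exp(-((x / 8.0) ** 2))
        fit = th.fit_two_term_gaussian(th.TemperatureProfile(x, y))
        assert fit.rms_residual < 1e-6
        np.testing.assert_allclose(fit(x), y, atol=1e-5)

    def test_too_few_points_rejected(self):
        prof = th.TemperatureProfile(np.arange(5.0), np.ones(5) * 23.0)
        with pytest.raises(ValueError, match=">= 7"):
            th.fit_two_term_gaussian(prof)
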