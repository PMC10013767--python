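"""Normalization schemes, background fits, severity, and mass calibration."""

import math

import numpy as np
import pytest

import ioplate as ip
from ioplate import pipeline, scenarios
from ioplate.errors import (
    DegenerateDenominatorError,
    EmptyResultError,
    InsufficientDataError,
    InvalidInputError,
)


def _flat_spectrum(value=1.0, fmax=100.0):
    freqs = np.arange(0.0, fmax + 1.0)
    return ip.Spectrum(freqs=freqs, psd=np.full_like(freqs, value), df=1.0)


def _exp_spectrum(a=1.0, b=-0.1, bump=0.0, bump_f=20.0, fmax=50.0):
    freqs = np.arange(0.0, fmax + 1.0)
    psd = a * np.exp(b * freqs) + bump * np.exp(-0.5 * (freqs - bump_f) ** 2)
    return ip.Spectrum(freqs=freqs, psd=psd, df=1.0)


class TestIopNormalize:
    def test_self_normalization(self, grid2_voltage):
        spec = ip.welch_psd(grid2_voltage)
        norm = ip.iop_normalize(spec)
        assert ip.band_power(norm, 40, 50) == pytest.approx(1.0, rel=1e-9)

    def test_scale_invariance(self):
        spec = _exp_spectrum(bump=0.5)
        scaled = ip.Spectrum(freqs=spec.freqs, psd=7.0 * spec.psd, df=1.0)
        np.testing.assert_allclose(ip.iop_normalize(spec).values,
                                   ip.iop_normalize(scaled).values, rtol=1e-12)

    def test_per_epoch_same_period_rule(self, grid2_voltage):
        sgram = ip.spectrogram(grid2_voltage, epoch_s=2.0)
        norm = ip.iop_normalize(sgram)
        for i in (0, sgram.n_epochs - 1):
            assert ip.band_power(norm.epoch(i), 40, 50) == pytest.approx(1.0)

    def test_zero_denominator_raises(self):
        spec = ip.Spectrum(freqs=np.arange(0.0, 101.0), psd=np.zeros(101), df=1.0)
        with pytest.raises(DegenerateDenominatorError):
            ip.iop_normalize(spec)

    def test_severity_invariant_across_locomotor_levels(self, plate):
        """Tremor severity is a property of the animal, not of how much it
        moved: 1x vs 3x activity gives equal severity within 10%."""
        sev = []
        for lvl in (1.0, 3.0):
            params = scenarios.grid2_params(duration_s=120.0, seed=11,
                                            locomotor_level=lvl)
            force, _, _ = ip.gen_mouse_motion(params)
            v = ip.simulate_plate(plate, force)
            sev.append(pipeline.analyze_force_plate(v)["severity"].value)
        assert sev[1] == pytest.approx(sev[0], rel=0.10)


class TestGeneralNormalize:
    @pytest.mark.parametrize("channel,band", [("video", (2.0, 30.0)),
                                              ("accelerometer", (2.0, 50.0))])
    def test_denominator_band(self, channel, band):
        spec = _exp_spectrum()
        norm = ip.general_normalize(spec, channel)
        assert norm.denominator == pytest.approx(ip.band_power(spec, *band))
        assert norm.bands["general"] == band

    def test_flat_spectrum_value_independent_of_level(self):
        for c in (1.0, 5.0):
            spec = _flat_spectrum(c)
            norm = ip.general_normalize(spec, "video")
            # 2-30 Hz inclusive: 29 bins x 1 Hz
            assert norm.values[10] == pytest.approx(1.0 / 29.0)

    def test_unknown_channel(self):
        with pytest.raises(InvalidInputError):
            ip.general_normalize(_flat_spectrum(), "emg")


class TestVelocityNormalize:
    def _sgram(self, n_epochs=3):
        freqs = np.arange(0.0, 31.0)
        rows = np.tile(np.linspace(1, 2, len(freqs)), (n_epochs, 1))
        times = np.array([(2.0 * i, 2.0 * (i + 1)) for i in range(n_epochs)])
        return ip.Spectrogram(epoch_times=times, freqs=freqs, rows=rows, df=1.0)

    def test_threshold_is_strictly_greater(self):
        """0.4 mm/s itself is 'not over' the threshold and is excluded."""
        norm = ip.velocity_normalize(self._sgram(), [0.3, 0.4, 0.5])
        assert norm.meta["n_kept"] == 1
        assert norm.meta["n_excluded"] == 2

    def test_equal_velocities_mean_over_v(self):
        sgram = self._sgram()
        norm = ip.velocity_normalize(sgram, [2.0, 2.0, 2.0])
        np.testing.assert_allclose(norm.values, sgram.rows.mean(axis=0) / 2.0)

    def test_zero_velocity_epoch_guarded(self):
        norm = ip.velocity_normalize(self._sgram(), [0.0, 1.0, 1.0])
        assert np.all(np.isfinite(norm.values))
        assert norm.meta["n_excluded"] == 1

    def test_all_excluded_raises(self):
        with pytest.raises(EmptyResultError):
            ip.velocity_normalize(self._sgram(), [0.1, 0.2, 0.0])


class TestBackgroundFit:
    def test_one_term_recovery(self):
        spec = _exp_spectrum(a=1.0, b=-0.1)
        fit = ip.fit_background(spec, "video")
        assert fit.params["a"] == pytest.approx(1.0, rel=0.01)
        assert fit.params["b"] == pytest.approx(-0.1, rel=0.01)
        mask = fit.support_mask
        np.testing.assert_allclose(fit.fitted_values[mask], spec.psd[mask],
                                   rtol=1e-6)

    def test_bump_in_excluded_band_ignored(self):
        clean = ip.fit_background(_exp_spectrum(a=1.0, b=-0.1), "accelerometer")
        bumped = ip.fit_background(_exp_spectrum(a=1.0, b=-0.1, bump=5.0),
                                   "accelerometer")
        for key in ("a", "b"):
            assert bumped.params[key] == pytest.approx(clean.params[key],
                                                       rel=0.02, abs=1e-6)

    def test_support_isolation(self):
        """Perturbing only inside an excluded band leaves the fit unchanged."""
        spec = _exp_spectrum(a=2.0, b=-0.08)
        fit0 = ip.fit_background(spec, "accelerometer")
        perturbed = spec.psd.copy()
        inside = (spec.freqs >= 14) & (spec.freqs <= 26)
        perturbed[inside] *= 50.0
        fit1 = ip.fit_background(
            ip.Spectrum(freqs=spec.freqs, psd=perturbed, df=1.0), "accelerometer")
        for key in fit0.params:
            assert abs(fit1.params[key] - fit0.params[key]) < 1e-9

    def test_flat_spectrum_near_constant(self):
        fit = ip.fit_background(_flat_spectrum(3.0, fmax=50.0), "video")
        assert fit.params["b"] == pytest.approx(0.0, abs=1e-3)
        np.testing.assert_allclose(fit.fitted_values, 3.0, rtol=0.01)

    def test_pchip_bridges_excluded_band(self):
        spec = _exp_spectrum(a=1.0, b=-0.05, bump=2.0)
        fit = ip.fit_background(spec, "force_plate")
        assert fit.model == "shape_preserving_interp"
        inside = (spec.freqs >= 12) & (spec.freqs <= 27)
        # interpolated background stays near the bump-free exponential
        np.testing.assert_allclose(fit.fitted_values[inside],
                                   np.exp(-0.05 * spec.freqs[inside]),
                                   rtol=0.05)


class TestSubtractBackground:
    def test_self_subtraction_zero(self):
        spec = _exp_spectrum(a=1.0, b=-0.1)
        fit = ip.fit_background(spec, "video")
        out = ip.subtract_background(spec, fit)
        assert np.all(out.psd[fit.support_mask] < 1e-6)

    def test_never_negative(self, grid2_voltage):
        spec = ip.welch_psd(grid2_voltage)
        fit = ip.fit_background(spec, "force_plate")
        out = ip.subtract_background(spec, fit)
        assert np.all(out.psd >= 0)

    def test_injected_bump_power_recovered(self):
        """A 20 Hz bump of known integrated power survives subtraction."""
        freqs = np.arange(0.0, 51.0)
        bump = 0.8 * np.exp(-0.5 * ((freqs - 20.0) / 1.5) ** 2)
        bump_power = bump.sum() * 1.0
        psd = 2.0 * np.exp(-0.06 * freqs) + bump
        spec = ip.Spectrum(freqs=freqs, psd=psd, df=1.0)
        fit = ip.fit_background(spec, "accelerometer")
        out = ip.subtract_background(spec, fit)
        assert ip.band_power(out, 15, 25) == pytest.approx(bump_power, rel=0.10)

    def test_grid_mismatch(self):
        fit = ip.fit_background(_exp_spectrum(), "video")
        other = _flat_spectrum(fmax=60.0)
        with pytest.raises(InvalidInputError):
            ip.subtract_background(other, fit)


class TestTremorSeverity:
    def test_peak_value_is_density_at_peak(self):
        freqs = np.arange(0.0, 51.0)
        psd = np.ones_like(freqs)
        psd[20] = 5.0
        norm = ip.iop_normalize(ip.Spectrum(freqs=freqs, psd=psd, df=1.0))
        sev = ip.tremor_severity(norm)
        assert sev.from_peak and sev.peak.freq == 20.0
        assert sev.value == pytest.approx(norm.values[20])

    def test_fallback_window_mean_flagged(self):
        freqs = np.arange(0.0, 51.0)
        psd = np.exp(-0.05 * freqs)  # monotone: no concave peak
        norm = ip.iop_normalize(ip.Spectrum(freqs=freqs, psd=psd, df=1.0))
        sev = ip.tremor_severity(norm)
        assert not sev.from_peak
        mask = (freqs >= 15) & (freqs <= 25)
        assert sev.value == pytest.approx(norm.values[mask].mean())

    def test_denominator_scaling(self):
        freqs = np.arange(0.0, 51.0)
        psd = np.ones_like(freqs)
        psd[20] = 5.0
        spec = ip.Spectrum(freqs=freqs, psd=psd, df=1.0)
        s1 = ip.tremor_severity(ip.iop_normalize(spec, iop_band=(40, 50)))
        s2 = ip.tremor_severity(ip.iop_normalize(spec, iop_band=(30, 50)))
        d1 = ip.band_power(spec, 40, 50)
        d2 = ip.band_power(spec, 30, 50)
        assert s2.value / s1.value == pytest.approx(d1 / d2)


class TestMassCalibration:
    def test_noiseless_inversion(self):
        """Forward-generated frequencies invert to the exact stiffness."""
        k_true = ip.stiffness_for_frequency(42.0, 0.5)
        added_g = np.array([0.0, 90.0, 190.0, 390.0, 590.0, 880.0])
        freqs = [ip.natural_frequency(
            ip.PlateConfig(mass_kg=0.5 + g * 1e-3, stiffness_N_per_m=k_true))
            for g in added_g]
        cal = ip.mass_calibration(added_g, freqs)
        assert cal.stiffness_N_per_m == pytest.approx(k_true, rel=1e-3)
        assert cal.baseline_mass_kg == pytest.approx(0.5, rel=1e-3)
        assert cal.r == pytest.approx(1.0, abs=1e-9)

    def test_noisy_series_high_correlation(self):
        """The six-mass series with measurement noise keeps r above 0.95."""
        k_true = ip.stiffness_for_frequency(42.0, 0.5)
        added_g = np.array([0.0, 90.0, 190.0, 390.0, 590.0, 880.0])
        rng = np.random.default_rng(4)
        freqs = [ip.natural_frequency(
            ip.PlateConfig(mass_kg=0.5 + g * 1e-3, stiffness_N_per_m=k_true))
            * (1 + 0.01 * rng.standard_normal()) for g in added_g]
        cal = ip.mass_calibration(added_g, freqs)
        assert cal.r > 0.95
        assert cal.ci95[0] < cal.r <= cal.ci95[1] + 1e-12

    def test_duplicate_masses_tolerated(self):
        cal = ip.mass_calibration([0.0, 0.0, 100.0, 200.0],
                                  [42.0, 41.5, 38.0, 35.0])
        assert cal.r < 1.0

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            ip.mass_calibration([0.0, 100.0], [42.0, 38.0])

    def test_nonpositive_frequency(self):
        with pytest.raises(InvalidInputError):
            ip.mass_calibration([0.0, 100.0, 200.0], [42.0, 0.0, 35.0])
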