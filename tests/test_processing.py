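"""Calibration, replicate summing, noise estimation, and the QC filters."""

import logging
import math

import numpy as np
import pytest

import t1screen as t
from t1screen.processing import CalibrationError, difference_spectrum
from t1screen.simulate import PeakSpec
from t1screen.spectra import SampleMeasurement
from t1screen.tables import PeakWindow

QUIET = t.NuisanceModel(noise_sd=0.0, shift_offset_sd=0.0)
AXIS = t.AxisSpec()


def render(peaks, spin_lock_ms, stage="short_a", **kwargs):
    return t.render_spectrum(peaks, spin_lock_ms, AXIS, QUIET, stage, **kwargs)


def make_measurement(amp, rate, role, sample_id, degradation=0.0, offset=0.0,
                     amp_scale=1.0, protein_id="", mix_id=""):
    peaks = [PeakSpec(5.0, amp * amp_scale, rate, degradation)] if amp else []
    common = dict(ppm_offset=offset, role=role, sample_id=sample_id,
                  protein_id=protein_id, mix_id=mix_id)
    return SampleMeasurement(
        sample_id=sample_id,
        role=role,
        short_a=render(peaks, 10.0, "short_a", **common),
        long=render(peaks, 200.0, "long", scan_factor=2.0, **common),
        short_b=render(peaks, 10.0, "short_b", **common),
        protein_id=protein_id,
        mix_id=mix_id,
    )


WINDOW = PeakWindow("met", "mix1", 4.975, 5.025, 5.0)


class TestCalibrate:
    def test_recovers_synthetic_offset_to_one_grid_step(self):
        spec = render([PeakSpec(5.0, 1.0, 0.0)], 10.0, ppm_offset=0.020)
        cal = t.calibrate(spec)
        dss_idx = int(np.argmax(cal.intensity * (np.abs(cal.ppm) < 0.1)))
        assert abs(cal.ppm[dss_idx]) <= AXIS.step + 1e-12
        assert cal.meta["calibration_shift_ppm"] == pytest.approx(0.020, abs=AXIS.step)

    def test_idempotent_on_calibrated_spectrum(self):
        spec = render([PeakSpec(5.0, 1.0, 0.0)], 10.0, ppm_offset=0.0)
        cal = t.calibrate(spec)
        assert cal.meta["calibration_shift_ppm"] == 0.0
        assert np.array_equal(cal.intensity, spec.intensity)

    def test_flat_spectrum_fails(self):
        flat = spec = t.Spectrum1D(
            "s", "M", "t1rho_short_a", 10, AXIS.build(), np.zeros(len(AXIS.build()))
        )
        with pytest.raises(CalibrationError, match="no reference peak"):
            t.calibrate(flat)

    def test_intensities_preserved(self):
        spec = render([PeakSpec(5.0, 1.0, 0.0)], 10.0, ppm_offset=0.02)
        cal = t.calibrate(spec)
        assert cal.intensity.max() == pytest.approx(spec.intensity.max())


class TestSumShortReplicates:
    def test_identical_replicates_double(self):
        a = render([PeakSpec(5.0, 1.0, 0.0)], 10.0)
        out = t.sum_short_replicates(a, a)
        assert out.window_max(4.9, 5.1) == pytest.approx(2.0)
        assert out.experiment == "t1rho_short_sum"

    def test_arithmetic(self):
        a = render([PeakSpec(5.0, 1.0, 0.0)], 10.0)
        b = render([PeakSpec(5.0, 0.9, 0.0)], 10.0)
        assert t.sum_short_replicates(a, b).window_max(4.9, 5.1) == pytest.approx(1.9)

    def test_axis_mismatch_rejected(self):
        a = render([PeakSpec(5.0, 1.0, 0.0)], 10.0)
        other_axis = t.AxisSpec(ppm_min=-0.5, ppm_max=11.2, step=0.002)
        b = t.render_spectrum(
            [PeakSpec(5.0, 1.0, 0.0)], 10.0, other_axis, QUIET, "short_a"
        )
        with pytest.raises(ValueError, match="axes"):
            t.sum_short_replicates(a, b)

    def test_requires_short_delay(self):
        a = render([PeakSpec(5.0, 1.0, 0.0)], 10.0)
        long = render([PeakSpec(5.0, 1.0, 0.0)], 200.0, "long")
        with pytest.raises(ValueError, match="10"):
            t.sum_short_replicates(a, long)


class TestStabilityFilter:
    @pytest.mark.parametrize(
        "amp_b, expected, unstable",
        [
            (1.00, 0.0, False),
            (0.94, 0.06 / 0.97, True),
            (0.97, 0.03 / 0.985, False),
        ],
    )
    def test_reldiff_boundaries(self, amp_b, expected, unstable):
        a = render([PeakSpec(5.0, 1.0, 0.0)], 10.0)
        b = render([PeakSpec(5.0, amp_b, 0.0)], 10.0)
        rd = t.stability_reldiff(a, b, WINDOW)
        assert rd == pytest.approx(expected, abs=1e-9)
        assert (rd > 0.05) is unstable


class TestGainFilter:
    @pytest.mark.parametrize(
        "pm_minus_p, flagged",
        [(1.0, False), (1.08, True), (1.03, False)],
    )
    def test_gain_boundaries(self, pm_minus_p, flagged):
        gain = t.gain_check(1.0, pm_minus_p, 0.0)
        assert gain == pytest.approx(1.0 - pm_minus_p)
        assert (gain < -0.05) is flagged


class TestEstimateNoise:
    def test_recovers_known_sd(self):
        rng = np.random.default_rng(0)
        axis = AXIS.build()
        spec = t.Spectrum1D(
            "s", "M", "t1rho_short_a", 10, axis, rng.normal(0, 0.01, len(axis))
        )
        assert t.estimate_noise(spec, (10.5, 11.0)) == pytest.approx(0.01, rel=0.3)

    def test_all_zero_region(self):
        axis = AXIS.build()
        spec = t.Spectrum1D("s", "M", "t1rho_short_a", 10, axis, np.zeros(len(axis)))
        assert t.estimate_noise(spec, (10.5, 11.0)) == 0.0

    def test_narrow_region_rejected(self):
        spec = render([PeakSpec(5.0, 1.0, 0.0)], 10.0)
        with pytest.raises(ValueError, match="<10|grid points"):
            t.estimate_noise(spec, (10.5, 10.502))

    def test_peak_in_region_logs_warning(self, caplog):
        noisy = t.NuisanceModel(noise_sd=0.005, shift_offset_sd=0.0)
        spec = t.render_spectrum(
            [PeakSpec(10.7, 1.0, 0.0)], 10.0, AXIS, noisy, "short_a", ppm_offset=0.0
        )
        with caplog.at_level(logging.WARNING):
            sd = t.estimate_noise(spec, (10.5, 11.0))
        assert sd > 0.005 * 3  # inflated
        assert any("peak-contaminated" in r.message for r in caplog.records)


class TestQuantifyPeak:
    def make_triple(self, pm_rate=1.0, pm_scale=1.0, degradation=0.0):
        m = make_measurement(1.0, 1.0, "M", "M_mix1", mix_id="mix1")
        p = make_measurement(0.0, 1.0, "P", "P_prot", protein_id="prot")
        pm = make_measurement(
            1.0, pm_rate, "PM", "PM_prot_mix1", amp_scale=pm_scale,
            degradation=degradation, protein_id="prot", mix_id="mix1",
        )
        return m, p, pm

    def test_noiseless_null_peak_is_low_snr(self):
        m, p, pm = self.make_triple()
        q = t.quantify_peak(m, p, pm, WINDOW)
        assert q.snr == 0.0
        assert q.flags == {"low_snr"}

    def test_strong_binder_with_noise_passes_all_filters(self):
        study = t.generate_study(
            ["prot1"],
            t.synthetic_library(1, seed=0),
            {"met1": "mix1"},
            t.BindingTruth(kd={("prot1", "met1"): 50.0}),
            t.NuisanceModel(noise_sd=0.005, shift_offset_sd=0.0, seed=3),
        )
        meas = {mm.role: mm for mm in study.measurements}
        meas = {
            role: t.calibrate_measurement(mm) for role, mm in meas.items()
        }
        anchor = study.peak_lists["met1"].peaks[0][0]
        window = PeakWindow("met1", "mix1", anchor - 0.025, anchor + 0.025, anchor)
        q = t.quantify_peak(meas["M"], meas["P"], meas["PM"], window)
        assert q.snr > 2
        assert q.flags == set()

    def test_degrading_metabolite_flagged_unstable(self):
        # ~10% loss between the two short replicates
        loss = 1.0 - math.sqrt(0.9)
        m, p, pm = self.make_triple(degradation=loss)
        q = t.quantify_peak(m, p, pm, WINDOW)
        assert "unstable" in q.flags
        assert q.stability_reldiff == pytest.approx(0.1 / 0.95, rel=1e-6)

    def test_cross_delay_comparison_refused(self):
        m, p, pm = self.make_triple()
        long400 = render([PeakSpec(5.0, 1.0, 1.0)], 400.0, "long", role="M",
                         sample_id="M400", mix_id="mix1")
        m400 = SampleMeasurement(
            sample_id="M400", role="M", short_a=m.short_a, short_b=m.short_b,
            long=long400, mix_id="mix1", long_delay_ms=400.0,
        )
        with pytest.raises(ValueError, match="long delay"):
            t.quantify_peak(m400, p, pm, WINDOW)

    def test_difference_of_identical_spectra_is_zero(self):
        a = render([PeakSpec(5.0, 1.0, 0.0)], 10.0)
        diff = difference_spectrum(a, a)
        assert np.all(diff.intensity == 0.0)
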