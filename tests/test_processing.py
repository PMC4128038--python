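"""Optical densities, rest-window calibration, and skin removal."""

import math

import numpy as np
import pytest

from nirsbf import (HRSeries, OpticalSeries, OpticsParams, calibrate_rest,
                    cbf_feedback_signal, extract_brain, make_subject,
                    optical_density, render_optics, simulate_truth)
from nirsbf.processing import BrainConcSeries, ODSeries


def _pipeline(subject, optics, schedule, duration, seed=0,
              rest_window=(0.0, 30.0), baseline="first-10s"):
    truth = simulate_truth(subject, duration, schedule, fs=optics.fs)
    op = render_optics(truth, optics, seed=seed)
    od = optical_density(op, baseline=baseline)
    calib = calibrate_rest(od, rest_window)
    brain = extract_brain(od, calib, optics)
    return truth, od, calib, brain


class TestOpticalDensity:
    def test_reference_intensity_gives_zero_od(self):
        n = 200
        op = OpticalSeries(np.arange(n) / 10.0, np.ones(n), np.ones(n),
                           fs=10.0)
        od = optical_density(op, baseline=(1.0, 1.0))
        assert np.allclose(od.x, 0.0)
        assert np.allclose(od.y, 0.0)

    def test_halved_intensity_gives_ln2(self):
        n = 20
        op = OpticalSeries(np.arange(n) / 10.0, np.full(n, 0.5),
                           np.full(n, 0.5), fs=10.0)
        od = optical_density(op, baseline=(1.0, 1.0))
        assert np.allclose(od.x, math.log(2.0))

    def test_default_baseline_is_first_ten_seconds(self):
        n = 300
        I = np.concatenate([np.full(100, 2.0), np.full(200, 1.0)])
        op = OpticalSeries(np.arange(n) / 10.0, I, I, fs=10.0)
        od = optical_density(op)
        assert np.allclose(od.x[:100], 0.0)
        assert np.allclose(od.x[100:], math.log(2.0))

    def test_bad_baseline_mode_rejected(self):
        n = 20
        op = OpticalSeries(np.arange(n) / 10.0, np.ones(n), np.ones(n),
                           fs=10.0)
        with pytest.raises(ValueError, match="baseline"):
            optical_density(op, baseline="bogus")


class TestCalibrateRest:
    def test_noiseless_rest_recovers_path_length_ratio(self, default_subject):
        optics = OpticsParams(noise_sd=0.0, pulse_amp=0.0)
        _, od, calib, _ = _pipeline(default_subject, optics,
                                    [("rest", 60.0)], 60.0,
                                    baseline=(1.0, 1.0))
        # constant c_brain during rest: slope = l_skin_3cm / l_1cm,
        # intercept = eps * c_brain * l_brain_3cm = 0 here
        assert calib.alpha == pytest.approx(
            optics.l_skin_3cm / optics.l_1cm, abs=1e-9)
        assert calib.beta == pytest.approx(0.0, abs=1e-9)
        assert calib.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_brain_offset_lands_in_intercept(self):
        optics = OpticsParams(noise_sd=0.0, pulse_amp=0.0)
        rng = np.random.default_rng(0)
        c_skin = 0.1 * rng.standard_normal(600)
        c_brain = np.full(600, 0.25)
        from nirsbf.hemodynamics import beer_lambert_intensities
        I1, I3 = beer_lambert_intensities(c_skin, c_brain, optics)
        op = OpticalSeries(np.arange(600) / 10.0, I1, I3, fs=10.0)
        od = optical_density(op, baseline=(1.0, 1.0))
        calib = calibrate_rest(od, (0.0, 60.0))
        assert calib.alpha == pytest.approx(1.2, abs=1e-9)
        assert calib.beta == pytest.approx(
            optics.epsilon * 0.25 * optics.l_brain_3cm, abs=1e-9)

    def test_recovers_slope_from_noisy_synthetic_line(self):
        rng = np.random.default_rng(1)
        x = 0.1 * rng.standard_normal(600)
        y = 1.2 * x + 0.05 + 0.005 * rng.standard_normal(600)
        od = ODSeries(np.arange(600) / 10.0, x, y, fs=10.0)
        calib = calibrate_rest(od, (0.0, 60.0))
        assert calib.alpha == pytest.approx(1.2, abs=0.05)
        assert calib.beta == pytest.approx(0.05, abs=0.01)

    def test_window_with_too_few_samples_rejected(self):
        od = ODSeries(np.arange(100) / 10.0, np.random.default_rng(0)
                      .standard_normal(100), np.zeros(100), fs=10.0)
        with pytest.raises(ValueError, match=">= 10"):
            calibrate_rest(od, (0.0, 0.25))

    def test_zero_variance_window_rejected(self):
        od = ODSeries(np.arange(100) / 10.0, np.zeros(100), np.zeros(100),
                      fs=10.0)
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_rest(od, (0.0, 10.0))


class TestExtractBrain:
    def test_null_brain_yields_null_estimate(self, default_subject):
        optics = OpticsParams()  # noisy
        _, _, _, brain = _pipeline(default_subject, optics,
                                   [("rest", 120.0)], 120.0, seed=3)
        noise_floor = optics.noise_sd / (optics.epsilon * optics.l_brain_3cm)
        assert abs(float(np.mean(brain.c_brain_hat))) < 3.0 * noise_floor

    def test_noiseless_step_recovered_exactly(self):
        s = make_subject({"response_time_constant": 0.5}, seed=4)
        optics = OpticsParams(noise_sd=0.0, pulse_amp=0.0)
        truth, _, _, brain = _pipeline(s, optics,
                                       [("rest", 30.0), ("raise", 60.0)],
                                       90.0)
        rest = truth.time_s <= 30.0
        ref = truth.c_brain - truth.c_brain[rest].mean()
        assert np.max(np.abs(brain.c_brain_hat - ref)) < 1e-9

    def test_estimate_invariant_to_extra_skin_fluctuation(self):
        # same cortical truth, different skin traces -> identical residual
        optics = OpticsParams(noise_sd=0.0, pulse_amp=0.0)
        s1 = make_subject({"skin_fluctuation_amp": 0.2}, seed=5)
        s2 = make_subject({"skin_fluctuation_amp": 0.6}, seed=6)
        sched = [("rest", 30.0), ("raise", 60.0)]
        _, _, _, b1 = _pipeline(s1, optics, sched, 90.0)
        _, _, _, b2 = _pipeline(s2, optics, sched, 90.0)
        assert np.max(np.abs(b1.c_brain_hat - b2.c_brain_hat)) < 1e-9

    def test_noisy_recovery_correlates_with_truth(self, default_subject):
        optics = OpticsParams()  # 0.5 % noise, pulsation on
        truth, _, _, brain = _pipeline(default_subject, optics,
                                       [("rest", 30.0), ("raise", 120.0)],
                                       150.0, seed=7)
        m = truth.time_s >= 30.0
        r = np.corrcoef(brain.c_brain_hat[m], truth.c_brain[m])[0, 1]
        assert r > 0.9


class TestFeedbackSignal:
    def _hr60(self):
        t = np.arange(1.0, 30.0)
        return HRSeries(beat_index=np.arange(1, len(t) + 1), t_s=t,
                        hr_per_s=np.ones(len(t)),
                        hr_per_min=np.full(len(t), 60.0))

    def test_zero_beats_is_identity(self):
        v = np.random.default_rng(0).standard_normal(100)
        brain = BrainConcSeries(np.arange(100) / 10.0, v, fs=10.0)
        out = cbf_feedback_signal(brain, None, smooth_beats=0)
        assert np.array_equal(out.c_brain_hat, v)

    def test_constant_input_preserved(self):
        brain = BrainConcSeries(np.arange(500) / 50.0, np.full(500, 2.5),
                                fs=50.0)
        out = cbf_feedback_signal(brain, self._hr60(), smooth_beats=2)
        assert np.allclose(out.c_brain_hat, 2.5)

    def test_cardiac_frequency_attenuated(self):
        # sinusoid at exactly the cardiac period, window = one period
        fs = 50.0
        t = np.arange(int(20 * fs)) / fs
        v = np.sin(2 * np.pi * 1.0 * t)
        brain = BrainConcSeries(t, v, fs=fs)
        out = cbf_feedback_signal(brain, self._hr60(), smooth_beats=1)
        core = slice(int(2 * fs), int(18 * fs))
        atten = np.max(np.abs(out.c_brain_hat[core])) / 1.0
        assert atten < 0.1

    def test_empty_hr_with_smoothing_rejected(self):
        brain = BrainConcSeries(np.arange(10) / 10.0, np.zeros(10), fs=10.0)
        with pytest.raises(ValueError, match="heart-rate"):
            cbf_feedback_signal(brain, HRSeries(), smooth_beats=1)
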