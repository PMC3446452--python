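"""Force-plate processing: filter response, stance detection,
normalization, and feature extraction against closed forms."""

import math

import numpy as np
import pandas as pd
import pytest

from ratgait import grf, synth
from ratgait.exceptions import (InsufficientDataError, NoContactError,
                                ParameterError)


def make_recording(t, fx=None, fy=None, fz=None, bw=2.5, fs=200.0):
    zero = np.zeros_like(t)
    data = pd.DataFrame({"time_s": t,
                         "fx_N": zero if fx is None else fx,
                         "fy_N": zero if fy is None else fy,
                         "fz_N": zero if fz is None else fz})
    return grf.GRFRecording(data=data, body_weight_N=bw, sample_rate_hz=fs)


def butterworth_filtfilt_gain(f, cutoff=25.0, order=4, fs=200.0):
    """Closed-form magnitude of the zero-phase (squared) digital response.

    The discrete filter maps analog frequencies through the bilinear
    transform, so the Butterworth magnitude is evaluated at prewarped
    frequencies tan(pi f / fs).
    """
    ratio = math.tan(math.pi * f / fs) / math.tan(math.pi * cutoff / fs)
    return 1.0 / (1.0 + ratio ** (2 * order))


class TestLowpassFilter:
    def test_dc_signal_unchanged(self):
        t = np.arange(0, 2, 1 / 200)
        rec = make_recording(t, fz=np.full_like(t, 1.3))
        out = grf.lowpass_filter(rec)
        assert out.data["fz_N"].to_numpy() == pytest.approx(1.3, abs=1e-9)

    @pytest.mark.parametrize("freq,bound,comparison,rel", [
        (5.0, 0.99, "greater", 0.02), (80.0, 0.01, "less", 0.25)])
    def test_amplitude_response_matches_closed_form(self, freq, bound,
                                                    comparison, rel):
        # deep-stopband residuals are at the numerical noise floor, hence
        # the looser relative tolerance for the 80-Hz case
        t = np.arange(0, 4, 1 / 200)
        rec = make_recording(t, fz=np.sin(2 * np.pi * freq * t))
        out = grf.lowpass_filter(rec).data["fz_N"].to_numpy()
        interior = slice(len(t) // 4, 3 * len(t) // 4)
        measured = np.max(np.abs(out[interior]))
        expected = butterworth_filtfilt_gain(freq)
        assert measured == pytest.approx(expected, rel=rel)
        if comparison == "greater":
            assert measured > bound
        else:
            assert measured < bound

    def test_cutoff_at_nyquist_rejected(self):
        t = np.arange(0, 1, 1 / 200)
        with pytest.raises(ParameterError):
            grf.lowpass_filter(make_recording(t), cutoff_hz=100.0)


class TestDetectStance:
    def test_half_sine_window_within_one_sample(self):
        fs = 200.0
        t = np.arange(0, 0.6, 1 / fs)
        fz = np.where((t >= 0.10) & (t <= 0.47),
                      2.0 * np.sin(np.pi * (t - 0.10) / 0.37), 0.0)
        window = grf.detect_stance(make_recording(t, fz=fz, fs=fs))
        assert window.start_s == pytest.approx(0.10, abs=1 / fs)
        assert window.end_s == pytest.approx(0.47, abs=1 / fs)

    def test_all_zero_trace_is_no_contact(self):
        t = np.arange(0, 0.5, 1 / 200)
        with pytest.raises(NoContactError):
            grf.detect_stance(make_recording(t))

    def test_longer_of_two_bumps_selected(self):
        fs = 200.0
        t = np.arange(0, 1.2, 1 / fs)
        short = ((t >= 0.1) & (t <= 0.2)) * np.sin(
            np.pi * (t - 0.1) / 0.1)
        long = ((t >= 0.5) & (t <= 0.9)) * np.sin(
            np.pi * (t - 0.5) / 0.4)
        window = grf.detect_stance(make_recording(t, fz=2 * (short + long),
                                                  fs=fs))
        assert window.start_s == pytest.approx(0.5, abs=1 / fs)
        assert window.end_s == pytest.approx(0.9, abs=1 / fs)


class TestNormalize:
    def test_forces_in_body_weight_units(self):
        t = np.arange(0, 0.5, 1 / 200)
        fz = np.where((t >= 0.1) & (t <= 0.4), 2.0, 0.0)
        rec = make_recording(t, fz=fz, bw=2.5)
        norm = grf.normalize(rec, grf.StanceWindow(0.1, 0.4))
        assert np.max(norm.fz) == pytest.approx(0.8)

    def test_midstance_time_maps_to_half(self):
        # 0.37-s stance: start + 0.185 s lands at tau = 0.5
        fs = 200.0
        t = np.arange(0, 0.7, 1 / fs)
        fz = np.where((t >= 0.1) & (t <= 0.47), t - 0.1, 0.0)
        rec = make_recording(t, fz=fz)
        norm = grf.normalize(rec, grf.StanceWindow(0.1, 0.47))
        mid = np.argmin(np.abs(norm.tau - 0.5))
        assert norm.fz[mid] * rec.body_weight_N == pytest.approx(0.185)

    def test_linear_ramp_resampled_exactly(self):
        t = np.arange(0, 0.5, 1 / 200)
        rec = make_recording(t, fz=3.0 * t + 0.2, bw=1.0)
        norm = grf.normalize(rec, grf.StanceWindow(0.1, 0.4))
        expected = 3.0 * (0.1 + norm.tau * 0.3) + 0.2
        assert norm.fz == pytest.approx(expected, abs=1e-12)

    def test_short_stance_rejected(self):
        t = np.arange(0, 0.5, 1 / 200)
        rec = make_recording(t, fz=np.ones_like(t))
        with pytest.raises(InsufficientDataError):
            grf.normalize(rec, grf.StanceWindow(0.1, 0.14))


def analytic_norm(fx=None, fy=None, fz=None, n=101, stance=0.37):
    tau = np.linspace(0, 1, n)
    zero = np.zeros_like(tau)
    return grf.NormalizedGRF(tau=tau,
                             fx=zero if fx is None else fx(tau),
                             fy=zero if fy is None else fy(tau),
                             fz=zero if fz is None else fz(tau),
                             stance_time_s=stance)


class TestExtractFeatures:
    def test_half_sine_vertical_closed_form(self):
        norm = analytic_norm(fz=lambda tau: 0.6 * np.sin(np.pi * tau))
        feats = grf.extract_features(norm)
        assert feats.peak_vertical == pytest.approx(0.6)
        assert feats.vertical_impulse == pytest.approx(0.3820, rel=1e-3)

    def test_sine_lobe_fore_aft_closed_form(self):
        norm = analytic_norm(
            fx=lambda tau: -0.1 * np.sin(2 * np.pi * tau),
            fz=lambda tau: 0.6 * np.sin(np.pi * tau))
        feats = grf.extract_features(norm)
        assert feats.peak_braking == pytest.approx(0.1, rel=1e-6)
        assert feats.peak_propulsive == pytest.approx(0.1, rel=1e-6)
        assert feats.braking_impulse == pytest.approx(0.03183, rel=1e-3)
        assert feats.propulsive_impulse == pytest.approx(0.03183, rel=1e-3)

    def test_mediolateral_peaks_split_at_midstance(self):
        norm = analytic_norm(
            fy=lambda tau: np.where(tau <= 0.5,
                                    0.04 * np.sin(2 * np.pi * tau),
                                    0.08 * np.sin(2 * np.pi * (tau - 0.5))),
            fz=lambda tau: 0.6 * np.sin(np.pi * tau))
        feats = grf.extract_features(norm)
        assert feats.peak_ml_first == pytest.approx(0.04, rel=1e-6)
        assert feats.peak_ml_second == pytest.approx(0.08, rel=1e-6)
        assert feats.ml_impulse == pytest.approx(0.12 / math.pi, rel=1e-3)

    def test_no_sign_change_reports_missing_not_zero(self):
        norm = analytic_norm(fx=lambda tau: -0.1 * np.sin(np.pi * tau),
                             fz=lambda tau: 0.6 * np.sin(np.pi * tau))
        feats = grf.extract_features(norm)
        assert "no_fx_zero_crossing" in feats.flags
        assert math.isnan(feats.peak_braking)
        assert math.isnan(feats.propulsive_impulse)

    def test_impulse_additivity_with_one_crossing(self):
        norm = analytic_norm(
            fx=lambda tau: np.where(tau <= 0.5,
                                    -0.12 * np.sin(2 * np.pi * tau),
                                    -0.07 * np.sin(2 * np.pi * tau)),
            fz=lambda tau: 0.6 * np.sin(np.pi * tau))
        feats = grf.extract_features(norm)
        total = np.trapezoid(np.abs(norm.fx), norm.tau)
        assert feats.braking_impulse + feats.propulsive_impulse == \
            pytest.approx(total, rel=1e-9)

    def test_low_vertical_impulse_warns(self):
        norm = analytic_norm(fz=lambda tau: 0.05 * np.sin(np.pi * tau))
        with pytest.warns(UserWarning, match="partial"):
            feats = grf.extract_features(norm)
        assert "low_vertical_impulse" in feats.flags


class TestPipelineRecovery:
    @pytest.mark.parametrize("fs,tol", [(200.0, 0.01), (2000.0, 0.001)])
    def test_generator_truth_recovered_on_analytic_curves(self, fs, tol):
        shape = synth.GRFShapeParams(peak_vertical=0.6, peak_braking=0.12,
                                     peak_propulsive=0.08,
                                     peak_ml_first=0.04,
                                     peak_ml_second=0.06,
                                     sample_rate_hz=fs, noise_sd_N=0.0)
        recording, truth = synth.gen_grf_curve(shape)
        analysis = grf.analyze_recording(recording, lowpass=False)
        for name in grf.GRFFeatures.FIELDS:
            assert getattr(analysis.features, name) == pytest.approx(
                getattr(truth, name), rel=tol), name

    def test_features_invariant_to_body_weight_and_stance_rescaling(self):
        base = synth.GRFShapeParams(body_weight_N=2.2, stance_time_s=0.30,
                                    noise_sd_N=0.0)
        scaled = synth.GRFShapeParams(body_weight_N=4.4, stance_time_s=0.60,
                                      noise_sd_N=0.0)
        feats = {}
        for label, shape in (("base", base), ("scaled", scaled)):
            rec, _ = synth.gen_grf_curve(shape)
            feats[label] = grf.analyze_recording(rec, lowpass=False).features
        for name in grf.GRFFeatures.FIELDS:
            assert getattr(feats["base"], name) == pytest.approx(
                getattr(feats["scaled"], name), rel=1e-3), name

    def test_filter_commutes_on_band_limited_curves(self):
        # smooth bump with zero edge slope: spectrum far below 25 Hz
        fs, stance = 1000.0, 0.5
        t = np.arange(0, 0.9, 1 / fs)
        tau = np.clip((t - 0.2) / stance, 0, 1)
        inside = (t >= 0.2) & (t <= 0.2 + stance)
        fz = np.where(inside, 1.5 * np.sin(np.pi * tau) ** 2, 0.0)
        fx = np.where(inside,
                      -0.25 * np.sin(2 * np.pi * tau)
                      * np.sin(np.pi * tau), 0.0)
        rec = make_recording(t, fx=fx, fz=fz, bw=2.5, fs=fs)
        raw = grf.analyze_recording(rec, lowpass=False).features
        filtered = grf.analyze_recording(rec, lowpass=True).features
        for name in grf.GRFFeatures.FIELDS:
            a, b = getattr(raw, name), getattr(filtered, name)
            if math.isnan(a):
                assert math.isnan(b)
                continue
            assert b == pytest.approx(a, rel=5e-3), name

    def test_noise_converges_with_sample_rate(self):
        shape = synth.GRFShapeParams(sample_rate_hz=2000.0, noise_sd_N=0.01,
                                     seed=4)
        recording, truth = synth.gen_grf_curve(shape)
        analysis = grf.analyze_recording(recording, lowpass=True)
        assert analysis.features.peak_vertical == pytest.approx(
            truth.peak_vertical, rel=0.05)
        assert analysis.features.vertical_impulse == pytest.approx(
            truth.vertical_impulse, rel=0.05)
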