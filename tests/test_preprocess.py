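import logging

import numpy as np
import pytest
from scipy.signal import freqz

from conftest import make_recording
from motioncue.preprocess import (
    PreprocessConfig,
    bandpass_filter,
    common_average_reference,
    design_bandpass,
    extract_motion_epochs,
    gaze_std_from_center,
    preprocess_session,
    remove_blink_artifacts,
    verify_condition,
)
from motioncue.synth import SynthConfig, generate_session


class TestCommonAverageReference:
    def test_identical_channels_become_zero(self):
        rec = make_recording(np.full((31, 100), 3.7))
        out = common_average_reference(rec)
        assert np.allclose(out.data, 0.0)

    def test_two_channel_closed_form(self):
        a, b = np.sin(np.linspace(0, 5, 200)), np.cos(np.linspace(0, 5, 200))
        out = common_average_reference(make_recording(np.stack([a, b])))
        assert np.allclose(out.data[0], a - (a + b) / 2)
        assert np.allclose(out.data[1], b - (a + b) / 2)

    def test_column_means_vanish_for_random_input(self):
        rng = np.random.default_rng(0)
        out = common_average_reference(make_recording(rng.normal(size=(31, 500))))
        assert np.abs(out.data.mean(axis=0)).max() < 1e-12

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            common_average_reference(make_recording(np.zeros((1, 10))))


@pytest.fixture(scope="module")
def response():
    taps = design_bandpass(PreprocessConfig(), 500.0)
    w, h = freqz(taps, worN=8192, fs=500.0)
    return w, np.abs(h)


class TestBandpassFilter:
    """The designed filter's own frequency response is the oracle here."""

    def _tone_gain(self, freq_hz: float) -> float:
        t = np.arange(20_000) / 500.0
        tone = np.sin(2 * np.pi * freq_hz * t)
        out = bandpass_filter(make_recording(np.tile(tone, (2, 1))))
        mid = slice(5000, 15000)  # avoid edge transients
        return float(np.abs(out.data[0, mid]).max())

    def test_5hz_passband_gain(self, response):
        w, mag = response
        single_pass = mag[np.argmin(np.abs(w - 5.0))]
        measured = self._tone_gain(5.0)
        # single application with group-delay removal: measured gain is the
        # designed filter's own magnitude response
        assert measured == pytest.approx(single_pass, abs=0.02)
        assert 0.7 <= measured <= 1.1

    def test_100hz_stopband_attenuation(self, response):
        w, mag = response
        single_pass = mag[np.argmin(np.abs(w - 100.0))]
        measured = self._tone_gain(100.0)
        assert measured == pytest.approx(single_pass, abs=1e-3)
        assert -20 * np.log10(max(measured, 1e-12)) >= 20.0

    def test_zero_input_zero_output(self):
        out = bandpass_filter(make_recording(np.zeros((3, 1000))))
        assert np.allclose(out.data, 0.0)

    def test_band_edges_must_fit_sample_rate(self):
        rec = make_recording(np.zeros((2, 1000)), fs=500.0)
        with pytest.raises(ValueError):
            bandpass_filter(rec, PreprocessConfig(bandpass_high_hz=300.0))


class TestEpochExtraction:
    def test_one_session_yields_33_epochs_13_features(self, default_session):
        recording, trials = default_session
        stack = extract_motion_epochs(recording, trials)
        assert stack.data.shape == (31, 33, 13)
        assert PreprocessConfig().n_features(500.0) == 13

    def test_stride_20_indices_recovered_from_ramp(self, default_session):
        recording, trials = default_session
        ramp = recording.copy_with(
            np.tile(np.arange(recording.n_samples, dtype=float), (31, 1))
        )
        stack = extract_motion_epochs(ramp, trials)
        onset = int(trials.iloc[0]["motion_onset_sample"])
        expected = onset + np.arange(0, 250 + 1, 20)
        row = stack.labels.index[stack.labels["trial_id"] == trials.iloc[0]["trial_id"]][0]
        assert np.array_equal(stack.data[0, row], expected)

    def test_constant_channel_gives_constant_features(self, default_session):
        recording, trials = default_session
        const = recording.copy_with(np.full_like(recording.data, 2.5, dtype=float))
        stack = extract_motion_epochs(const, trials)
        assert np.allclose(stack.data, 2.5)

    def test_incomplete_window_dropped_with_warning(self, default_session, caplog):
        recording, trials = default_session
        cut = int(trials.iloc[-1]["motion_onset_sample"]) + 100
        truncated = recording.copy_with(np.asarray(recording.data)[:, :cut])
        with caplog.at_level(logging.WARNING):
            stack = extract_motion_epochs(truncated, trials)
        assert stack.n_trials == len(trials) - 1
        assert "dropping trial" in caplog.text

    def test_filter_then_epoch_free_of_boundary_leakage(self, default_session):
        recording, trials = default_session
        whole = extract_motion_epochs(bandpass_filter(recording), trials)
        pad = 500  # 1 s on each side, far beyond the FIR's +/-25-sample memory
        t = trials.iloc[10]
        onset = int(t["motion_onset_sample"])
        seg = recording.copy_with(
            np.asarray(recording.data, dtype=float)[:, onset - pad : onset + 250 + pad]
        )
        seg_f = bandpass_filter(seg)
        local = np.asarray(seg_f.data)[:, pad : pad + 251 : 20]
        row = whole.labels.index[whole.labels["trial_id"] == t["trial_id"]][0]
        scale = np.abs(whole.data[:, row]).max()
        assert np.abs(whole.data[:, row] - local).max() / scale < 1e-6


class TestGazeScreening:
    def test_constant_trace_zero_dispersion(self):
        assert gaze_std_from_center(np.full((100, 2), 0.4)) == pytest.approx(0.0, abs=1e-12)
        assert verify_condition(0.0) == "eye_fixed"

    def test_symmetric_four_point_closed_form(self):
        d = 0.05
        trace = np.array([[d, 0], [-d, 0], [0, d], [0, -d]]) + 0.5
        assert gaze_std_from_center(trace) == pytest.approx(d)

    def test_threshold_classification(self):
        assert verify_condition(0.029) == "eye_fixed"
        assert verify_condition(0.031) == "eye_tracking"

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            gaze_std_from_center(np.empty((0, 2)))


class TestBlinkRemoval:
    def test_injected_blinks_removed_from_frontal_channels(self, blink_session):
        recording, _ = blink_session
        onsets = recording.annotations["blink_onsets"]
        assert onsets.size >= 3, "fixture should contain several blinks"
        referenced = common_average_reference(recording)
        cleaned, info = remove_blink_artifacts(referenced)
        assert info["converged"]
        assert len(info["removed_components"]) >= 1
        frontal = [recording.channel_labels.index(lab) for lab in ("Fp1", "Fp2")]
        windows = np.concatenate([np.arange(o, o + 250) for o in onsets])
        before = np.asarray(referenced.data, dtype=float)[frontal][:, windows].var()
        after = np.asarray(cleaned.data, dtype=float)[frontal][:, windows].var()
        assert after <= 0.2 * before  # >= 80 % variance reduction

    def test_no_blinks_means_near_identity(self, short_protocol):
        cfg = SynthConfig(protocol=short_protocol, blink_rate_hz=0.0, seed=21)
        recording, _ = generate_session(cfg, "eye_fixed", 21)
        referenced = common_average_reference(recording)
        cleaned, info = remove_blink_artifacts(referenced)
        x = np.asarray(referenced.data, dtype=float)
        y = np.asarray(cleaned.data, dtype=float)
        for ch in range(x.shape[0]):
            r = np.corrcoef(x[ch], y[ch])[0, 1]
            assert r >= 0.99

    def test_pipeline_reports_gaze_verification(self, default_session):
        recording, _ = default_session
        _, info = preprocess_session(recording, skip_ica=True)
        assert info["verified_condition"] == "eye_fixed"
        assert info["gaze_dispersion"] < 0.030
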