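"""Feature-extraction checks: filter response, segmentation accuracy,
smoothed peak semantics, and lag-domain f0 estimation."""

import numpy as np
import pytest
from scipy import signal

from thermobuzz.extraction import (BuzzSegment, ExtractionConfig, Waveform,
                                   extract_features, fundamental_frequency,
                                   highpass, peak_acceleration, per_bee_means,
                                   quefrency_resolution, segment_buzzes)
from thermobuzz.synthetic import (BuzzSpec, RecordingPlan,
                                  generate_ground_truth_manifest,
                                  synthesize_recording)

FS = 20480.0
CFG = ExtractionConfig()


def tone(freq, dur=1.0, amp=1.0, fs=FS, phase=0.0):
    t = np.arange(int(dur * fs)) / fs
    return Waveform(amp * np.sin(2 * np.pi * freq * t + phase), fs)


def designed_gain(freq, fs=FS):
    """Oracle: frequency response of a Hann local-mean-removal kernel,
    computed from the closed-form 1 - W(f) with W the normalised Hann
    window's transfer function (independent of the convolution path)."""
    n = 513
    win = np.hanning(n) / np.hanning(n).sum()
    k = np.arange(n) - n // 2
    return abs(1.0 - np.sum(win * np.exp(-2j * np.pi * freq * k / fs)))


class TestHighpass:
    def test_dc_rejected(self):
        w = Waveform(np.full(4096, 5.0), FS)
        out = highpass(w, CFG)
        assert abs(out.samples[512:-512].mean()) < 1e-6

    def test_passband_tone_amplitude_matches_designed_response(self):
        out = highpass(tone(200.0), CFG)
        mid = out.samples[2048:-2048]
        amp = np.abs(mid).max()
        assert amp == pytest.approx(designed_gain(200.0), rel=0.02)
        assert amp == pytest.approx(1.0, rel=0.02)

    def test_stopband_tone_suppressed(self):
        out = highpass(tone(1.0, dur=2.0), CFG)
        assert np.abs(out.samples[4096:-4096]).max() < 0.05
        assert designed_gain(1.0) < 0.05

    def test_zero_phase_no_onset_shift(self):
        x = np.zeros(8192)
        x[4096:] = np.sin(2 * np.pi * 200 * np.arange(4096) / FS)
        out = highpass(Waveform(x, FS), CFG)
        # energy before the true onset is only filter leakage, centred
        pre = np.abs(out.samples[: 4096 - 256])
        assert pre.max() < 0.05

    def test_too_short_signal_errors(self):
        with pytest.raises(ValueError, match="shorter than"):
            highpass(Waveform(np.ones(100), FS), CFG)

    def test_length_preserved(self):
        w = tone(150.0, dur=0.5)
        assert highpass(w, CFG).samples.size == w.samples.size


class TestSegmentation:
    def test_silent_recording_yields_nothing(self):
        assert segment_buzzes(Waveform(np.zeros(4096), FS), CFG) == []

    def test_minimum_duration_filter(self):
        plan = RecordingPlan(
            buzzes=[BuzzSpec(2.0, 0.05, 200.0, 100.0),
                    BuzzSpec(10.0, 0.5, 200.0, 100.0),
                    BuzzSpec(20.0, 2.0, 200.0, 100.0)],
            total_duration=60.0, noise_sd=0.5, seed=3)
        w = synthesize_recording(plan)
        segs = segment_buzzes(highpass(w, CFG), CFG)
        assert len(segs) == 2
        assert segs[0].duration >= CFG.min_duration

    def test_onsets_within_25ms_of_manifest(self, matched_plan, matched_recording):
        man = generate_ground_truth_manifest(matched_plan)
        segs = segment_buzzes(highpass(matched_recording, CFG), CFG)
        assert len(segs) == len(man)
        for seg, (_, row) in zip(segs, man.iterrows()):
            assert abs(seg.start_time - row.onset_s) <= 0.025
            end_true = row.onset_s + row.duration_s
            assert abs(seg.start_time + seg.duration - end_true) <= 0.025

    def test_segments_disjoint_ordered_in_bounds(self, matched_recording):
        segs = segment_buzzes(highpass(matched_recording, CFG), CFG)
        for a, b in zip(segs, segs[1:]):
            assert a.end_sample <= b.start_sample
        assert all(0 <= s.start_sample < s.end_sample <= matched_recording.samples.size
                   for s in segs)


class TestPeakAcceleration:
    def test_sine_peak_matches_two_sample_mean(self):
        w = tone(200.0)
        seg = BuzzSegment(0, w.samples.size, w)
        x = np.abs(w.samples)
        oracle = np.max((x[:-1] + x[1:]) / 2.0)
        assert peak_acceleration(seg, CFG) == pytest.approx(oracle, rel=1e-12)
        assert peak_acceleration(seg, CFG) == pytest.approx(1.0, rel=0.01)

    def test_homogeneous_degree_one(self):
        w = tone(200.0)
        w3 = Waveform(3.0 * w.samples, FS)
        s, s3 = BuzzSegment(0, w.samples.size, w), BuzzSegment(0, w.samples.size, w3)
        assert peak_acceleration(s3, CFG) == pytest.approx(3 * peak_acceleration(s, CFG))

    def test_isolated_spike_halved_by_smoother(self):
        x = np.zeros(1000)
        x[500] = 7.0
        seg = BuzzSegment(0, 1000, Waveform(x, FS))
        assert peak_acceleration(seg, CFG) == pytest.approx(3.5)


class TestFundamentalFrequency:
    def test_grand_mean_tone_within_one_bin(self, tone_recording):
        feats = extract_features(tone_recording, CFG)
        assert len(feats) == 1
        assert abs(feats[0].f0 - 217.0) <= quefrency_resolution(217.0, FS)

    def test_f0_not_spectral_peak(self):
        # strongest energy on the 3rd harmonic: f0 must still read 150
        t = np.arange(int(2 * FS)) / FS
        x = (0.3 * np.sin(2 * np.pi * 150 * t)
             + 0.4 * np.sin(2 * np.pi * 300 * t)
             + 1.0 * np.sin(2 * np.pi * 450 * t))
        w = Waveform(x, FS)
        est = fundamental_frequency(BuzzSegment(0, x.size, w), CFG)
        assert abs(est - 150.0) <= quefrency_resolution(150.0, FS)
        # brute-force oracle: full-signal autocorrelation maximum
        acf = np.correlate(x, x, "full")[x.size - 1:]
        lags = np.arange(x.size)
        lo, hi = int(FS / 1000), int(FS / 50)
        lag = lo + np.argmax(acf[lo:hi])
        assert abs(FS / lag - 150.0) < 5.0

    def test_tone_above_cap_flagged_missing(self):
        w = tone(1500.0, dur=2.0)
        assert np.isnan(fundamental_frequency(BuzzSegment(0, w.samples.size, w), CFG))

    def test_random_tones_recovered_within_one_bin(self):
        # lag-domain estimates need >= 2 periods per 512-sample frame,
        # hence the 85 Hz floor (the study's buzzes sit at 81-444 Hz)
        rng = np.random.default_rng(12)
        for f0 in rng.uniform(85.0, 1000.0, 20):
            w = tone(f0, dur=0.5, phase=rng.uniform(0, 2 * np.pi))
            est = fundamental_frequency(BuzzSegment(0, w.samples.size, w), CFG)
            assert abs(est - f0) <= quefrency_resolution(f0, FS), f0

    def test_segment_shorter_than_window_errors(self):
        w = tone(200.0, dur=0.02)
        with pytest.raises(ValueError, match="analysis window"):
            fundamental_frequency(BuzzSegment(0, w.samples.size, w), CFG)

    def test_scale_invariance(self):
        w = tone(217.0)
        w2 = Waveform(37.0 * w.samples, FS)
        a = fundamental_frequency(BuzzSegment(0, w.samples.size, w), CFG)
        b = fundamental_frequency(BuzzSegment(0, w.samples.size, w2), CFG)
        assert a == pytest.approx(b, abs=1e-9)


class TestExtractFeatures:
    def test_empty_recording(self):
        assert extract_features(Waveform(np.zeros(4096), FS), CFG) == []

    def test_round_trip_against_manifest(self, matched_plan, matched_recording):
        man = generate_ground_truth_manifest(matched_plan)
        feats = extract_features(matched_recording, CFG)
        assert len(feats) == len(man)
        for f, (_, row) in zip(feats, man.iterrows()):
            assert abs(f.duration - row.duration_s) <= 0.05
            assert f.peak_accel == pytest.approx(row.peak_accel_ms2, rel=0.05)
            assert abs(f.f0 - row.f0_hz) <= quefrency_resolution(row.f0_hz, FS) + 1.0

    def test_silence_padding_invariance(self, tone_recording):
        feats = extract_features(tone_recording, CFG)
        padded = Waveform(
            np.concatenate([np.zeros(20480), tone_recording.samples, np.zeros(20480)]),
            FS)
        feats_p = extract_features(padded, CFG)
        assert len(feats) == len(feats_p) == 1
        assert feats_p[0].duration == pytest.approx(feats[0].duration, abs=1e-3)
        assert feats_p[0].peak_accel == pytest.approx(feats[0].peak_accel, rel=1e-6)
        assert feats_p[0].f0 == pytest.approx(feats[0].f0, abs=0.5)
        assert feats_p[0].start_time == pytest.approx(feats[0].start_time + 1.0, abs=1e-3)


class TestPerBeeMeans:
    def test_identical_buzzes_mean_is_common_value(self):
        from thermobuzz.extraction import BuzzFeatures
        feats = [BuzzFeatures(0.5, 80.0, 200.0)] * 4
        rec = per_bee_means(feats, "b1")
        assert rec["duration"] == 0.5 and rec["acceleration"] == 80.0
        assert rec["frequency"] == 200.0 and rec["n_buzzes"] == 4

    def test_two_frequencies_average(self):
        from thermobuzz.extraction import BuzzFeatures
        feats = [BuzzFeatures(0.3, 50.0, 100.0), BuzzFeatures(0.5, 70.0, 300.0)]
        assert per_bee_means(feats, "b")["frequency"] == pytest.approx(200.0)

    def test_matches_brute_force_recomputation(self, matched_recording):
        feats = extract_features(matched_recording, CFG)
        rec = per_bee_means(feats, "b")
        assert rec["duration"] == pytest.approx(
            sum(f.duration for f in feats) / len(feats))
        assert rec["acceleration"] == pytest.approx(
            sum(f.peak_accel for f in feats) / len(feats))
        valid = [f.f0 for f in feats if np.isfinite(f.f0)]
        assert rec["frequency"] == pytest.approx(sum(valid) / len(valid))

    def test_flagged_f0_excluded_from_mean(self):
        from thermobuzz.extraction import BuzzFeatures
        feats = [BuzzFeatures(0.3, 50.0, 100.0),
                 BuzzFeatures(0.5, 70.0, np.nan, f0_valid=False)]
        assert per_bee_means(feats, "b")["frequency"] == pytest.approx(100.0)

    def test_no_buzzes_yields_missing_record(self):
        rec = per_bee_means([], "b")
        assert rec["n_buzzes"] == 0 and np.isnan(rec["frequency"])
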