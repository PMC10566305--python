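"""Detector contracts: wavelet power, thresholding, segmentation, rejection,
and end-to-end fidelity against generator ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from swdkit.detect import (
    DetectorConfig,
    band_power,
    compute_threshold,
    cwt_power,
    default_freq_grid,
    detect_swd,
    detection_metrics,
    reject_artifacts,
    segment_events,
)
from swdkit.simulate import GeneratorConfig, generate_session, synth_swd
from swdkit.types import EEGRecording, EventInterval, ValidationError


def rec_from(x, rate=200.0):
    return EEGRecording(samples=np.asarray(x, dtype=float), sampling_rate_hz=rate)


def brute_force_segment(P, times, theta, merge_gap, min_dur):
    """Independent oracle: explicit run-length scan over the trace."""
    dt = times[1] - times[0]
    runs = []
    i = 0
    n = len(P)
    while i < n:
        if P[i] > theta:
            j = i
            while j < n and P[j] > theta:
                j += 1
            runs.append([times[i], times[j - 1] + dt])
            i = j
        else:
            i += 1
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged if e - s >= min_dur - 1e-9]


class TestCwtPower:
    def test_unit_sinusoid_localizes_at_nearest_grid_point(self):
        grid = default_freq_grid()
        t = np.arange(0, 20, 1 / 200.0)
        pts = cwt_power(rec_from(np.sin(2 * np.pi * 8 * t)), grid)
        mean_power = pts.power[800:-800].mean(axis=0)
        best = pts.freqs_hz[np.argmax(mean_power)]
        nearest = grid[np.argmin(np.abs(grid - 8.0))]
        assert best == nearest

    def test_zero_signal_gives_zero_power(self):
        pts = cwt_power(rec_from(np.zeros(2000)))
        assert np.allclose(pts.power, 0.0)

    def test_two_tone_gives_two_local_maxima_matching_fft(self):
        t = np.arange(0, 30, 1 / 200.0)
        x = np.sin(2 * np.pi * 8 * t) + np.sin(2 * np.pi * 30 * t)
        pts = cwt_power(rec_from(x))
        mean_power = pts.power[1000:-1000].mean(axis=0)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(mean_power)
        top2 = sorted(pts.freqs_hz[peaks[np.argsort(mean_power[peaks])[::-1][:2]]])
        # FFT oracle: the two dominant spectral lines
        freqs = np.fft.rfftfreq(len(x), 1 / 200.0)
        spec = np.abs(np.fft.rfft(x))
        fft_top2 = sorted(freqs[np.argsort(spec)[::-1][:2]])
        assert fft_top2 == pytest.approx([8.0, 30.0], abs=0.2)
        assert top2[0] == pytest.approx(8.0, rel=0.05)
        assert top2[1] == pytest.approx(30.0, rel=0.05)

    def test_frequency_above_nyquist_rejected(self):
        with pytest.raises(ValidationError, match="Nyquist"):
            cwt_power(rec_from(np.zeros(1000)), np.array([10.0, 150.0]))

    def test_swd_power_concentrated_in_analysis_band(self):
        cfg = GeneratorConfig()
        x = synth_swd(3.0, cfg, rate_hz=200.0)
        pts = cwt_power(rec_from(x))
        inside = band_power(pts, 5, 32).mean()
        total = band_power(pts, 2, 64).mean()
        assert inside / total > 0.9


class TestThreshold:
    def test_constant_trace_threshold_is_median(self):
        with pytest.warns(UserWarning, match="constant"):
            assert compute_threshold(np.full(100, 3.5), k=6) == 3.5

    def test_gaussian_trace_matches_sigma_scaling(self):
        rng = np.random.default_rng(0)
        P = rng.standard_normal(200_000)
        theta = compute_threshold(P, k=6)
        assert theta == pytest.approx(6.0, abs=0.05)

    def test_affine_equivariance(self):
        rng = np.random.default_rng(1)
        P = rng.exponential(size=5000)
        assert compute_threshold(10 * P, 6) == pytest.approx(10 * compute_threshold(P, 6), rel=1e-12)


class TestSegmentation:
    def test_sub_second_run_dropped(self):
        dt = 0.01
        times = np.arange(0, 15, dt)
        P = np.zeros_like(times)
        P[(times >= 2.0) & (times < 2.5)] = 10
        P[(times >= 10.0) & (times < 13.0)] = 10
        events = segment_events(P, times, 1.0, merge_gap_s=0.3, min_duration_s=1.0)
        assert len(events) == 1
        assert events[0].start_s == pytest.approx(10.0, abs=dt)
        assert events[0].end_s == pytest.approx(13.0, abs=dt)

    def test_short_gap_merged(self):
        dt = 0.01
        times = np.arange(0, 10, dt)
        P = np.zeros_like(times)
        P[(times >= 5.0) & (times < 6.0)] = 10
        P[(times >= 6.2) & (times < 7.5)] = 10
        events = segment_events(P, times, 1.0, merge_gap_s=0.3, min_duration_s=1.0)
        assert len(events) == 1
        assert events[0].start_s == pytest.approx(5.0, abs=dt)
        assert events[0].end_s == pytest.approx(7.5, abs=dt)

    def test_all_subthreshold_gives_empty(self):
        times = np.arange(0, 10, 0.01)
        assert segment_events(np.zeros_like(times), times, 1.0) == []

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        data=st.lists(st.integers(min_value=0, max_value=5), min_size=20, max_size=400),
        theta=st.integers(min_value=0, max_value=4),
        merge_gap=st.sampled_from([0.0, 0.1, 0.3, 0.7]),
        min_dur=st.sampled_from([0.5, 1.0, 2.0]),
    )
    def test_matches_brute_force_oracle(self, data, theta, merge_gap, min_dur):
        P = np.array(data, dtype=float)
        times = np.arange(len(P)) * 0.1
        got = segment_events(P, times, float(theta), merge_gap, min_dur)
        expected = brute_force_segment(P, times, float(theta), merge_gap, min_dur)
        assert [(e.start_s, e.end_s) for e in got] == pytest.approx(expected)
        for e in got:
            assert e.duration_s >= min_dur - 1e-9


class TestArtifactRejection:
    def test_white_noise_burst_rejected_swd_kept(self):
        cfg = GeneratorConfig()
        rate = 200.0
        rng = np.random.default_rng(0)
        x = np.zeros(int(30 * rate))
        swd = synth_swd(3.0, cfg, rate_hz=rate)
        x[int(5 * rate) : int(5 * rate) + len(swd)] += swd
        x[int(20 * rate) : int(22 * rate)] += rng.normal(0, 5 * cfg.swd_amplitude_uv, int(2 * rate))
        pts = cwt_power(rec_from(x), default_freq_grid(2, 88))
        intervals = [EventInterval(5.0, 8.0), EventInterval(20.0, 22.0)]
        kept, rejected = reject_artifacts(pts, intervals)
        assert kept == [intervals[0]]
        assert rejected == [intervals[1]]

    def test_empty_interval_list(self):
        pts = cwt_power(rec_from(np.zeros(1000)), default_freq_grid(2, 88))
        assert reject_artifacts(pts, []) == ([], [])


class TestDetectionMetrics:
    def test_perfect_prediction(self):
        evs = [EventInterval(1, 3), EventInterval(5, 8)]
        m = detection_metrics(evs, evs)
        assert m.precision == m.recall == 1.0

    def test_empty_prediction_flagged(self):
        m = detection_metrics([], [EventInterval(1, 3)])
        assert m.recall == 0.0 and m.precision == 0.0
        assert "undefined" in m.note

    def test_shift_beyond_tolerance_fails_to_match(self):
        truth = [EventInterval(10, 12)]
        pred = [EventInterval(13.1, 15.1)]
        m = detection_metrics(pred, truth, tolerance_s=0.5)
        assert m.precision == 0.0 and m.recall == 0.0


class TestEndToEnd:
    def test_recall_precision_on_synthetic_session(self, ko_session, ko_detection):
        events, _ = ko_detection
        m = detection_metrics(events, ko_session.events, tolerance_s=0.5)
        assert m.recall >= 0.9
        assert m.precision >= 0.9

    def test_detected_durations_at_least_min(self, ko_detection):
        events, _ = ko_detection
        assert all(e.duration_s >= 1.0 for e in events)
        starts = [e.start_s for e in events]
        assert starts == sorted(starts)

    def test_scale_invariance(self):
        ses = generate_session("ko", 0.1, seed=11)
        a = detect_swd(ses.recording)
        scaled = ses.recording.with_samples(ses.recording.samples * 10.0)
        b = detect_swd(scaled)
        assert [(e.start_s, e.end_s) for e in a] == [(e.start_s, e.end_s) for e in b]

    def test_false_positive_rate_on_event_free_session(self):
        cfg = GeneratorConfig(swd_rate_per_h=0.0)
        ses = generate_session(cfg, 0.5, seed=2)
        events = detect_swd(ses.recording)
        assert len(events) / 0.5 <= 2.0

    def test_threshold_monotonicity(self, ko_session):
        rec = ko_session.recording
        n_events, total_dur = [], []
        for k in (4.0, 6.0, 9.0):
            evs = detect_swd(rec, DetectorConfig(threshold_k=k))
            n_events.append(len(evs))
            total_dur.append(sum(e.duration_s for e in evs))
        assert n_events[0] >= n_events[1] >= n_events[2]
        assert total_dur[0] >= total_dur[1] >= total_dur[2]

    def test_too_short_recording_rejected(self):
        with pytest.raises(ValidationError, match="10 s"):
            detect_swd(rec_from(np.zeros(1000), rate=1000.0))
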