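"""Generator contracts: state dynamics, waveform morphology, ground truth."""

import math

import numpy as np
import pytest
from scipy import signal as sps

from swdkit.simulate import (
    CalibrationError,
    GeneratorConfig,
    config_from_targets,
    generate_session,
    get_preset,
    preset_names,
    sample_state_sequence,
    synth_background,
    synth_swd,
)
from swdkit.types import ValidationError


def welch_peak(x, fs, fmin=1.0, fmax=None):
    f, p = sps.welch(x, fs=fs, nperseg=int(fs), noverlap=int(fs) // 2)
    mask = (f >= fmin) & (f <= (fmax or fs / 2))
    return f[mask][np.argmax(p[mask])]


class TestStateSequence:
    def test_infinite_awake_dwell_gives_all_awake(self):
        cfg = GeneratorConfig(state_dwell_means_s={"awake": math.inf, "nrem": 180, "rem": 60})
        states = sample_state_sequence(cfg, 1.0, seed=0)
        assert set(states) == {"awake"}

    def test_same_seed_same_sequence(self):
        cfg = GeneratorConfig()
        a = sample_state_sequence(cfg, 2.0, seed=7)
        b = sample_state_sequence(cfg, 2.0, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_rem_entered_only_from_nrem_and_starts_awake(self):
        cfg = GeneratorConfig()
        states = sample_state_sequence(cfg, 5.0, seed=3)
        assert states[0] == "awake"
        for prev, cur in zip(states[:-1], states[1:]):
            if cur == "rem":
                assert prev in ("nrem", "rem")

    def test_mean_awake_dwell_matches_configured_exponential(self):
        # Monte-Carlo: pooled awake dwell mean ~ epoch-rounded exponential mean
        cfg = GeneratorConfig()
        dwells = []
        for seed in range(150):
            states = sample_state_sequence(cfg, 1.0, seed=seed)
            run = 0
            for lab in states:
                if lab == "awake":
                    run += 1
                elif run:
                    dwells.append(run * cfg.epoch_length_s)
                    run = 0
        expected = cfg.mean_epoch_dwell_s("awake")
        assert np.mean(dwells) == pytest.approx(expected, rel=0.10)


class TestBackground:
    @pytest.mark.parametrize("state,peak_hz", [("nrem", 3.0), ("rem", 7.0), ("awake", 30.0)])
    def test_single_state_psd_peak(self, state, peak_hz):
        cfg = GeneratorConfig()
        states = np.array([state] * 30, dtype=object)  # 5 min
        x = synth_background(states, cfg, seed=1)
        assert welch_peak(x, cfg.sampling_rate_hz, 1.0, 64.0) == pytest.approx(peak_hz, abs=0.5)

    def test_awake_rms_smaller_than_nrem(self):
        cfg = GeneratorConfig()
        awake = synth_background(np.array(["awake"] * 30, dtype=object), cfg, seed=2)
        nrem = synth_background(np.array(["nrem"] * 30, dtype=object), cfg, seed=2)
        assert np.sqrt(np.mean(awake**2)) < np.sqrt(np.mean(nrem**2))

    def test_zero_amplitudes_give_zero_signal(self):
        cfg = GeneratorConfig(
            background_amplitudes_uv={"awake": 0, "nrem": 0, "rem": 0},
            pink_noise_amplitude_uv=0,
        )
        x = synth_background(np.array(["awake", "nrem"], dtype=object), cfg, seed=0)
        assert np.all(x == 0)


class TestSWDWaveform:
    def test_single_harmonic_is_pure_tapered_cosine(self):
        cfg = GeneratorConfig(swd_n_harmonics=1)
        x = synth_swd(2.0, cfg)
        t = np.arange(len(x)) / cfg.sampling_rate_hz
        ref = cfg.swd_amplitude_uv * np.cos(2 * np.pi * cfg.swd_f0_hz * t)
        n_tap = int(cfg.swd_taper_s * cfg.sampling_rate_hz)
        np.testing.assert_allclose(x[n_tap:-n_tap], ref[n_tap:-n_tap], atol=1e-9)

    def test_psd_peaks_at_fundamental_and_first_harmonic(self):
        cfg = GeneratorConfig()
        x = synth_swd(3.0, cfg)
        f, p = sps.welch(x, fs=cfg.sampling_rate_hz, nperseg=1000, noverlap=500)
        peaks, _ = sps.find_peaks(p)
        top2 = peaks[np.argsort(p[peaks])[::-1][:2]]
        assert sorted(f[top2]) == pytest.approx([8.0, 16.0], abs=1.0)

    def test_crest_amplitude_matches_harmonic_sum(self):
        # at times where every harmonic cosine equals 1 the waveform reaches
        # A * sum(decay^(k-1)); oracle: dense evaluation of the closed form
        cfg = GeneratorConfig()
        x = synth_swd(3.0, cfg)
        expected = cfg.swd_amplitude_uv * sum(
            cfg.swd_harmonic_decay**k for k in range(cfg.swd_n_harmonics)
        )
        assert np.max(x) == pytest.approx(expected, rel=1e-6)
        # peak-to-trough: trough from dense evaluation of the harmonic sum
        t = np.linspace(0, 1 / cfg.swd_f0_hz, 100001)
        wave = sum(
            cfg.swd_harmonic_decay**k * np.cos(2 * np.pi * (k + 1) * cfg.swd_f0_hz * t)
            for k in range(cfg.swd_n_harmonics)
        )
        # trough falls between samples at 1 kHz; allow sample-resolution slack
        assert np.min(x) == pytest.approx(cfg.swd_amplitude_uv * np.min(wave), rel=2e-3)

    def test_sub_second_duration_refused(self):
        with pytest.raises(ValidationError):
            synth_swd(0.8, GeneratorConfig())


class TestSession:
    def test_zero_rate_gives_no_events(self):
        cfg = GeneratorConfig(swd_rate_per_h=0.0, artifact_rate_per_h=0.0)
        ses = generate_session(cfg, 0.05, seed=0)
        assert ses.events == [] and ses.artifacts == []

    def test_same_seed_bit_identical(self):
        a = generate_session("ko", 0.1, seed=5)
        b = generate_session("ko", 0.1, seed=5)
        np.testing.assert_array_equal(a.recording.samples, b.recording.samples)
        assert a.events == b.events and a.artifacts == b.artifacts

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_truth_events_inside_awake_epochs_and_disjoint(self, seed):
        ses = generate_session("ko", 0.2, seed=seed)
        epoch = ses.recording.epoch_length_s
        for ev in ses.events:
            assert ev.duration_s >= 1.0
            first = int(ev.start_s // epoch)
            last = int((ev.end_s - 1e-9) // epoch)
            assert all(ses.states[i] == "awake" for i in range(first, last + 1))
        for a, b in zip(ses.events[:-1], ses.events[1:]):
            assert b.start_s >= a.end_s

    def test_event_count_tracks_poisson_mean(self):
        # Monte-Carlo over seeds: mean events per awake hour ~ configured rate
        cfg = GeneratorConfig(swd_rate_per_h=40.0, artifact_rate_per_h=0.0)
        counts, awake_h = [], []
        for seed in range(60):
            ses = generate_session(cfg, 0.5, seed=seed)
            counts.append(len(ses.events))
            frac = np.mean(np.asarray(ses.states, dtype=object) == "awake")
            awake_h.append(0.5 * float(frac))
        rate = np.sum(counts) / np.sum(awake_h)
        assert rate == pytest.approx(40.0, rel=0.10)

    def test_pooled_swd_spectrum_peaks_at_f0_and_harmonic(self):
        from swdkit.events import concatenate_intervals

        ses = generate_session("ko", 0.25, seed=9)
        x = concatenate_intervals(ses.recording, ses.events)
        f, p = sps.welch(x, fs=1000.0, nperseg=1000, noverlap=500)
        band = (f >= 2) & (f <= 64)
        fb, pb = f[band], p[band]
        assert fb[np.argmax(pb)] == pytest.approx(8.0, abs=0.5)
        peaks, _ = sps.find_peaks(pb)
        top2 = peaks[np.argsort(pb[peaks])[::-1][:2]]
        assert 16.0 in [pytest.approx(v, abs=1.0) for v in fb[top2]] or sorted(fb[top2])[1] == pytest.approx(16.0, abs=1.0)


class TestPresetsAndTargets:
    def test_all_presets_resolve(self):
        for name in preset_names():
            p = get_preset(name)
            assert p.config.swd_rate_per_h > 0
            assert p.config.median_swd_duration_s() == pytest.approx(
                p.targets["median_duration_s"], rel=1e-9
            )

    def test_degenerate_spread_targets_give_zero_sigma(self):
        # mean == median -> sigma -> 0
        cfg = config_from_targets(
            {"median_duration_s": 2.0, "events_per_h": 60.0, "accumulated_s_per_h": 120.0}
        )
        assert cfg.swd_duration_lognorm_sigma == pytest.approx(0.0, abs=1e-9)

    def test_mean_below_median_is_infeasible(self):
        with pytest.raises(CalibrationError):
            config_from_targets(
                {"median_duration_s": 3.0, "events_per_h": 60.0, "accumulated_s_per_h": 120.0}
            )

    def test_ko_targets_identify_positive_sigma(self):
        cfg = config_from_targets(
            {"median_duration_s": 2.3, "events_per_h": 61.0, "accumulated_s_per_h": 155.0}
        )
        assert cfg.swd_duration_lognorm_sigma > 0
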