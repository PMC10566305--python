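"""Wavelet band-power SWD detection.

The detector mirrors the classic offline workflow for rodent spike-wave
discharges: high-pass the raw trace, continuous Morlet wavelet transform,
collapse spectral power over the 5–32 Hz band (the interval holding most of
the SWD oscillation power), threshold the band-power trace, segment
supra-threshold runs into events, drop anything shorter than 1 s, and
reject broadband mechanical artifacts (cable taps, pellet chewing) by a
high-band/analysis-band power ratio.

The threshold rule is robust — median + k scaled-MAD of the band-power
trace — so that it stays put even when discharges occupy a few percent of
the session.  Multiplying the input by any positive constant scales median
and MAD of power together, so the detected intervals are invariant under
amplitude rescaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pywt

from .events import SWDEvent, dominant_frequency, event_psd, harmonic_ratio
from .preprocess import highpass, resample
from .types import EEGRecording, EventInterval, ValidationError

__all__ = [
    "PowerTimeSeries",
    "DetectorConfig",
    "DetectionMetrics",
    "default_freq_grid",
    "cwt_power",
    "band_power",
    "compute_threshold",
    "segment_events",
    "reject_artifacts",
    "detect_swd",
    "detection_metrics",
]

MAD_SCALE = 1.4826  # MAD -> sigma for Gaussian data


@dataclass
class PowerTimeSeries:
    """Time × frequency wavelet power (µV²) on a log-spaced frequency grid."""

    times_s: np.ndarray
    freqs_hz: np.ndarray
    power: np.ndarray  # shape (n_times, n_freqs), nonnegative

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        if np.any(np.diff(self.times_s) <= 0) or np.any(np.diff(self.freqs_hz) <= 0):
            raise ValidationError("time and frequency grids must be strictly increasing")
        if self.power.shape != (len(self.times_s), len(self.freqs_hz)):
            raise ValidationError("power must have shape (n_times, n_freqs)")

    @property
    def dt_s(self) -> float:
        return float(self.times_s[1] - self.times_s[0])


@dataclass
class DetectorConfig:
    """All detector knobs.

    ``threshold_k`` scales the robust MAD threshold; ``merge_gap_s`` joins
    candidates split by brief power dips (shorter than the 1 s minimum so it
    cannot by itself promote two sub-threshold fragments into an event).
    """

    band_low_hz: float = 5.0
    band_high_hz: float = 32.0
    threshold_k: float = 6.0
    merge_gap_s: float = 0.3
    min_duration_s: float = 1.0
    artifact_band_hz: tuple[float, float] = (40.0, 80.0)
    artifact_power_ratio: float = 1.0
    wavelet_omega0: float = 6.0
    highpass_cutoff_hz: float = 0.9
    #: internal analysis rate; the band grid tops out below its Nyquist
    analysis_rate_hz: float = 200.0
    freq_min_hz: float = 2.0
    voices_per_octave: int = 8

    def __post_init__(self) -> None:
        if not (self.band_low_hz < self.band_high_hz < self.artifact_band_hz[0]):
            raise ValidationError("need band_low < band_high < artifact band")
        if not self.min_duration_s > 0:
            raise ValidationError("min_duration_s must be positive")
        if not self.threshold_k > 0:
            raise ValidationError("threshold_k must be positive")
        if self.merge_gap_s < 0:
            raise ValidationError("merge_gap_s must be nonnegative")
        if self.artifact_band_hz[1] >= self.analysis_rate_hz / 2:
            raise ValidationError("artifact band must lie below the analysis Nyquist")


def default_freq_grid(
    fmin_hz: float = 2.0, fmax_hz: float = 64.0, voices_per_octave: int = 8
) -> np.ndarray:
    """Log-spaced frequency grid, ``voices_per_octave`` points per octave."""
    n = int(np.floor(voices_per_octave * np.log2(fmax_hz / fmin_hz) + 1e-9)) + 1
    return fmin_hz * 2.0 ** (np.arange(n) / voices_per_octave)


def _morlet_wavelet(omega0: float) -> pywt.ContinuousWavelet:
    # cmorB-C: exp(2j*pi*C*t) exp(-t^2/B); B=2, C=omega0/2pi matches the
    # analytic Morlet with unit-variance Gaussian envelope.
    fc = omega0 / (2 * np.pi)
    return pywt.ContinuousWavelet(f"cmor2.0-{fc:.12f}")


def cwt_power(
    rec: EEGRecording,
    freq_grid: Optional[np.ndarray] = None,
    omega0: float = 6.0,
) -> PowerTimeSeries:
    """|Morlet wavelet coefficient|² per (time, frequency).

    Scales map to Fourier frequencies via the standard Morlet relation, and
    coefficients are normalized so a unit-amplitude sinusoid at a grid
    frequency yields power ≈ 1 (its maximum over frequency) at that grid
    point.
    """
    freqs = np.asarray(freq_grid if freq_grid is not None else default_freq_grid(), dtype=float)
    fs = rec.sampling_rate_hz
    if freqs.max() >= fs / 2:
        raise ValidationError(
            f"grid frequency {freqs.max():.1f} Hz at or above Nyquist ({fs / 2:.1f} Hz)"
        )
    wavelet = _morlet_wavelet(omega0)
    fc = omega0 / (2 * np.pi)
    scales = fc * fs / freqs
    power = np.empty((rec.n_samples, len(freqs)), dtype=np.float32)
    # chunk over scales to bound memory on long sessions
    chunk = 8
    for i in range(0, len(scales), chunk):
        sc = scales[i : i + chunk]
        coef, _ = pywt.cwt(rec.samples, sc, wavelet, method="fft")
        amp = 2.0 * np.abs(coef) / np.sqrt(sc)[:, None]
        power[:, i : i + chunk] = (amp.T ** 2).astype(np.float32)
    return PowerTimeSeries(times_s=rec.times_s, freqs_hz=freqs, power=power)


def band_power(pts: PowerTimeSeries, low_hz: float = 5.0, high_hz: float = 32.0) -> np.ndarray:
    """Band power trace P(t): trapezoidal integral of power over [low, high] Hz."""
    mask = (pts.freqs_hz >= low_hz) & (pts.freqs_hz <= high_hz)
    if mask.sum() < 2:
        raise ValidationError(f"band [{low_hz}, {high_hz}] Hz covers <2 grid frequencies")
    return np.trapezoid(pts.power[:, mask].astype(np.float64), pts.freqs_hz[mask], axis=1)


def compute_threshold(P: np.ndarray, k: float = 6.0) -> float:
    """Robust threshold median(P) + k · 1.4826 · MAD(P)."""
    P = np.asarray(P, dtype=float)
    if len(P) == 0:
        raise ValidationError("empty band-power trace")
    med = float(np.median(P))
    mad = float(np.median(np.abs(P - med)))
    if mad == 0:
        warnings.warn("constant band-power trace; threshold equals the median", stacklevel=2)
    return med + k * MAD_SCALE * mad


def segment_events(
    P: np.ndarray,
    times_s: np.ndarray,
    threshold: float,
    merge_gap_s: float = 0.3,
    min_duration_s: float = 1.0,
) -> list[EventInterval]:
    """Supra-threshold runs → merged candidates → ≥ min-duration events.

    Maximal runs with ``P > threshold`` become candidate half-open
    intervals; candidates separated by a gap shorter than ``merge_gap_s``
    are merged (gap absorbed); candidates shorter than ``min_duration_s``
    are discarded.
    """
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    P = np.asarray(P, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    if len(P) != len(times_s):
        raise ValidationError("P and times_s must have equal length")
    above = P > threshold
    if not above.any():
        return []
    dt = float(times_s[1] - times_s[0]) if len(times_s) > 1 else 0.0
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)  # exclusive index
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(P))
    candidates = [(times_s[i], times_s[j - 1] + dt) for i, j in zip(starts, ends)]
    merged: list[list[float]] = []
    for s, e in candidates:
        if merged and s - merged[-1][1] < merge_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [
        EventInterval(s, e, label="swd")
        for s, e in merged
        if e - s >= min_duration_s - 1e-9
    ]


def reject_artifacts(
    pts: PowerTimeSeries,
    intervals: Sequence[EventInterval],
    config: Optional[DetectorConfig] = None,
) -> tuple[list[EventInterval], list[EventInterval]]:
    """Split candidate intervals into (kept, rejected).

    An interval is rejected iff its power integrated over the artifact band
    (default 40–80 Hz) exceeds ``artifact_power_ratio`` times its power over
    the analysis band (5–32 Hz).  Broadband impulses fail this test;
    spike-wave events, whose harmonics sit below 32 Hz, pass.
    """
    cfg = config or DetectorConfig()
    lo, hi = cfg.artifact_band_hz
    if pts.freqs_hz.max() < hi:
        raise ValidationError("power grid does not cover the artifact band")
    kept: list[EventInterval] = []
    rejected: list[EventInterval] = []
    for iv in intervals:
        mask_t = (pts.times_s >= iv.start_s - 1e-9) & (pts.times_s < iv.end_s - 1e-9)
        spec = pts.power[mask_t].astype(np.float64).mean(axis=0)
        band_mask = (pts.freqs_hz >= cfg.band_low_hz) & (pts.freqs_hz <= cfg.band_high_hz)
        art_mask = (pts.freqs_hz >= lo) & (pts.freqs_hz <= hi)
        band = np.trapezoid(spec[band_mask], pts.freqs_hz[band_mask])
        art = np.trapezoid(spec[art_mask], pts.freqs_hz[art_mask])
        (rejected if art > cfg.artifact_power_ratio * band else kept).append(iv)
    return kept, rejected


def detect_swd(
    rec: EEGRecording,
    config: Optional[DetectorConfig] = None,
    return_report: bool = False,
):
    """Run the full detection pipeline on a recording.

    highpass → resample to the analysis rate → wavelet power → 5–32 Hz band
    power → robust threshold → segmentation (merge gap, ≥ 1 s rule) →
    artifact rejection → per-event spectral characterization.

    Returns a sorted list of :class:`~swdkit.events.SWDEvent`; with
    ``return_report=True`` also a dict with the threshold, the fraction of
    supra-threshold time and the rejection count.
    """
    cfg = config or DetectorConfig()
    if rec.duration_s < 10:
        raise ValidationError("detection needs at least 10 s of data")
    filtered = highpass(rec, cfg.highpass_cutoff_hz)
    work = resample(filtered, cfg.analysis_rate_hz)
    # grid spans freq_min up to just past the artifact band top
    n_oct = np.log2(cfg.artifact_band_hz[1] / cfg.freq_min_hz)
    n = int(np.ceil(cfg.voices_per_octave * n_oct)) + 1
    grid = cfg.freq_min_hz * 2.0 ** (np.arange(n) / cfg.voices_per_octave)
    pts = cwt_power(work, grid, omega0=cfg.wavelet_omega0)
    P = band_power(pts, cfg.band_low_hz, cfg.band_high_hz)
    theta = compute_threshold(P, cfg.threshold_k)
    candidates = segment_events(P, pts.times_s, theta, cfg.merge_gap_s, cfg.min_duration_s)
    kept, rejected_iv = reject_artifacts(pts, candidates, cfg)
    events = []
    for iv in kept:
        spectrum = event_psd(filtered, iv)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_dom = dominant_frequency(spectrum, (cfg.band_low_hz, cfg.band_high_hz))
            hr = harmonic_ratio(spectrum, f_dom)
        mask_t = (pts.times_s >= iv.start_s - 1e-9) & (pts.times_s < iv.end_s - 1e-9)
        events.append(
            SWDEvent(
                interval=iv,
                dominant_freq_hz=f_dom,
                harmonic_ratio=hr,
                mean_band_power=float(P[mask_t].mean()),
            )
        )
    events.sort(key=lambda e: e.start_s)
    if return_report:
        report = {
            "threshold": float(theta),
            "threshold_k": cfg.threshold_k,
            "band_hz": [cfg.band_low_hz, cfg.band_high_hz],
            "frac_supra_threshold": float(np.mean(P > theta)),
            "n_candidates": len(candidates),
            "n_rejected_artifacts": len(rejected_iv),
            "n_events": len(events),
        }
        return events, report
    return events


@dataclass
class DetectionMetrics:
    """Interval-level precision/recall against ground truth."""

    precision: float
    recall: float
    f1: float
    matches: list[tuple[int, int]] = field(default_factory=list)
    note: str = ""


def _intervals(seq) -> list[EventInterval]:
    return [e.interval if isinstance(e, SWDEvent) else e for e in seq]


def detection_metrics(
    predicted: Sequence[Union[EventInterval, SWDEvent]],
    truth: Sequence[Union[EventInterval, SWDEvent]],
    tolerance_s: float = 0.5,
) -> DetectionMetrics:
    """Greedy one-to-one matching of predicted vs true intervals.

    A pair matches when midpoints are within ``tolerance_s`` or when the
    overlap covers ≥ 50% of the shorter interval.
    """
    pred = _intervals(predicted)
    true = _intervals(truth)
    used = np.zeros(len(pred), dtype=bool)
    matches: list[tuple[int, int]] = []
    for ti, t in enumerate(true):
        best, best_ov = None, -1.0
        for pi, p in enumerate(pred):
            if used[pi]:
                continue
            ov = t.overlap_s(p)
            ok = abs(t.midpoint_s - p.midpoint_s) <= tolerance_s or (
                ov >= 0.5 * min(t.duration_s, p.duration_s)
            )
            if ok and ov > best_ov:
                best, best_ov = pi, ov
        if best is not None:
            used[best] = True
            matches.append((best, ti))
    n_match = len(matches)
    note = ""
    if len(pred) == 0 and len(true) == 0:
        return DetectionMetrics(1.0, 1.0, 1.0, [], "both lists empty")
    if len(pred) == 0:
        note = "no predictions; precision undefined, reported as 0"
        precision = 0.0
    else:
        precision = n_match / len(pred)
    recall = n_match / len(true) if len(true) else 1.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return DetectionMetrics(precision, recall, f1, matches, note)
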