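"""Per-event spectral characterization, per-session summaries, and
stimulus-locked interruption classification.

An SWD (spike-wave discharge) in the rat oscillates at roughly 8 Hz with a
prominent first harmonic at 16 Hz — the harmonic is what the spiky waveform
shape looks like in the spectrum — so each detected event is annotated with
its dominant frequency, a 2·f0/f0 harmonic power ratio, and its mean
5–32 Hz band power.  Session summaries mirror the standard reporting for
chronic recordings: events per hour, accumulated SWD seconds per hour,
median duration, and a 1-s-binned duration histogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import signal as sps

from .types import EEGRecording, EventInterval, StimulusLog, ValidationError

__all__ = [
    "SWDEvent",
    "SessionStats",
    "InterruptionResult",
    "HalfSessionCounts",
    "event_psd",
    "dominant_frequency",
    "harmonic_ratio",
    "session_statistics",
    "classify_interruption",
    "case2_ratio_by_half",
    "concatenate_intervals",
]

ANALYSIS_BAND = (5.0, 32.0)


@dataclass(frozen=True)
class SWDEvent:
    """A detected spike-wave discharge with optional spectral metrics."""

    interval: EventInterval
    dominant_freq_hz: Optional[float] = None
    harmonic_ratio: Optional[float] = None
    mean_band_power: Optional[float] = None

    @property
    def start_s(self) -> float:
        return self.interval.start_s

    @property
    def end_s(self) -> float:
        return self.interval.end_s

    @property
    def duration_s(self) -> float:
        return self.interval.duration_s


def _durations(events: Sequence[Union[EventInterval, SWDEvent]]) -> np.ndarray:
    return np.array([e.duration_s for e in events], dtype=float)


def _interval(e: Union[EventInterval, SWDEvent]) -> EventInterval:
    return e.interval if isinstance(e, SWDEvent) else e


@dataclass
class SessionStats:
    """Per-session SWD summary (rates normalized per hour)."""

    n_events: int
    recording_h: float
    events_per_h: float
    accumulated_s_per_h: float
    median_duration_s: Optional[float]
    #: counts per 1-s duration bin [1,2), [2,3), ..., [9,10), [10, inf)
    duration_histogram: np.ndarray = field(default_factory=lambda: np.zeros(10, dtype=int))

    HIST_EDGES = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, np.inf])


def session_statistics(
    events: Sequence[Union[EventInterval, SWDEvent]],
    recording_h: float,
) -> SessionStats:
    """Summarize one session's events.

    Per-hour figures are normalized to total recording time.  An empty event
    list yields zero rates and a missing (``None``) median.
    """
    if not recording_h > 0:
        raise ValidationError("recording_h must be positive")
    durations = _durations(events)
    hist, _ = np.histogram(durations, bins=SessionStats.HIST_EDGES)
    return SessionStats(
        n_events=len(durations),
        recording_h=recording_h,
        events_per_h=len(durations) / recording_h,
        accumulated_s_per_h=float(durations.sum()) / recording_h,
        median_duration_s=float(np.median(durations)) if len(durations) else None,
        duration_histogram=hist,
    )


def event_psd(
    rec: EEGRecording,
    interval: Union[EventInterval, Sequence[EventInterval]],
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density of the samples inside an interval.

    Uses 1 s Hann segments with 50% overlap, giving ≤ 1 Hz resolution.  A
    sequence of intervals is concatenated first (used for pooled SWD
    spectra).  Returns ``(freqs_hz, psd)``.
    """
    if isinstance(interval, (EventInterval,)):
        intervals = [interval]
    else:
        intervals = [_interval(iv) for iv in interval]
    for iv in intervals:
        if iv.start_s < -1e-9 or iv.end_s > rec.duration_s + 1e-9:
            raise ValidationError(f"interval [{iv.start_s}, {iv.end_s}) outside recording")
    x = concatenate_intervals(rec, intervals)
    nperseg = int(round(rec.sampling_rate_hz))
    nperseg = min(nperseg, len(x))
    if nperseg < 2:
        raise ValidationError("interval too short for a PSD")
    freqs, psd = sps.welch(
        x, fs=rec.sampling_rate_hz, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    return freqs, psd


def concatenate_intervals(rec: EEGRecording, intervals: Sequence[EventInterval]) -> np.ndarray:
    """Concatenate the raw samples of several intervals."""
    if not intervals:
        return np.array([])
    return np.concatenate([rec.segment(iv.start_s, iv.end_s) for iv in intervals])


def dominant_frequency(
    spectrum: tuple[np.ndarray, np.ndarray],
    band: tuple[float, float] = ANALYSIS_BAND,
) -> float:
    """Frequency of the spectral maximum within ``band``."""
    freqs, psd = spectrum
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not mask.any():
        raise ValidationError(f"spectrum does not cover band {band}")
    f_band, p_band = freqs[mask], psd[mask]
    if np.allclose(p_band, p_band[0]):
        warnings.warn("flat spectrum in band; returning the lowest band frequency", stacklevel=2)
        return float(f_band[0])
    return float(f_band[np.argmax(p_band)])


def harmonic_ratio(spectrum: tuple[np.ndarray, np.ndarray], f0: float, half_width_hz: float = 1.0) -> float:
    """Power in ``2·f0 ± 1 Hz`` divided by power in ``f0 ± 1 Hz``.

    A pure sinusoid gives ≈ 0; the default spike-wave morphology
    (amplitude decay 0.5 per harmonic) gives ≈ 0.25; broadband noise ≈ 1.
    """
    freqs, psd = spectrum
    if 2 * f0 + half_width_hz > freqs[-1]:
        raise ValidationError("spectrum does not cover the first harmonic")

    def band_int(fc: float) -> float:
        mask = (freqs >= fc - half_width_hz) & (freqs <= fc + half_width_hz)
        return float(np.trapezoid(psd[mask], freqs[mask])) if mask.sum() > 1 else float(psd[mask].sum())

    denom = band_int(f0)
    num = band_int(2 * f0)
    if denom == 0:
        warnings.warn("zero power at the fundamental; harmonic ratio undefined", stacklevel=2)
        return float("inf")
    return num / denom


# ---------------------------------------------------------------------------
# stimulus-interruption classification


@dataclass
class InterruptionResult:
    """Case 1 / Case 2 classification of stimulated SWDs.

    Case 1: the event ended within ``window_s`` of the first in-event
    stimulus (readily interrupted).  Case 2: it outlasted the window.
    Events with no stimulus onset inside them are flagged unstimulated and
    excluded from the ratio.  ``case2_ratio`` is ``None`` when no event was
    stimulated.
    """

    cases: list[Optional[str]]  # per event: "case1" | "case2" | None (unstimulated)
    window_s: float
    n_case1: int
    n_case2: int
    n_unstimulated: int

    @property
    def case2_ratio(self) -> Optional[float]:
        denom = self.n_case1 + self.n_case2
        return self.n_case2 / denom if denom else None


def classify_interruption(
    events: Sequence[Union[EventInterval, SWDEvent]],
    stimuli: StimulusLog,
    window_s: float = 1.5,
) -> InterruptionResult:
    """Classify each stimulated event as interrupted (Case 1) or not (Case 2).

    An event is stimulated iff at least one stimulus onset lies inside
    ``[start_s, end_s)``; with ``t*`` its first such onset, the event is
    Case 1 if ``end_s <= t* + window_s``, else Case 2.
    """
    onsets = np.asarray(stimuli.onsets_s, dtype=float)
    cases: list[Optional[str]] = []
    n1 = n2 = n0 = 0
    for e in events:
        iv = _interval(e)
        inside = onsets[(onsets >= iv.start_s) & (onsets < iv.end_s)]
        if len(inside) == 0:
            cases.append(None)
            n0 += 1
        elif iv.end_s <= inside[0] + window_s:
            cases.append("case1")
            n1 += 1
        else:
            cases.append("case2")
            n2 += 1
    return InterruptionResult(cases=cases, window_s=window_s, n_case1=n1, n_case2=n2, n_unstimulated=n0)


@dataclass
class HalfSessionCounts:
    """Event counts (total and Case 2) split at the session midpoint."""

    first_total: int
    second_total: int
    first_case2: int
    second_case2: int
    first_ratio: Optional[float]
    second_ratio: Optional[float]


def case2_ratio_by_half(
    events: Sequence[Union[EventInterval, SWDEvent]],
    stimuli: StimulusLog,
    session_duration_h: float,
    window_s: float = 1.5,
) -> HalfSessionCounts:
    """Partition events at the session midpoint (by start time) and count
    totals and Case 2 events per half."""
    if not session_duration_h > 0:
        raise ValidationError("session_duration_h must be positive")
    mid_s = session_duration_h * 3600.0 / 2.0
    res = classify_interruption(events, stimuli, window_s=window_s)
    first = [(e, c) for e, c in zip(events, res.cases) if _interval(e).start_s < mid_s]
    second = [(e, c) for e, c in zip(events, res.cases) if _interval(e).start_s >= mid_s]

    def counts(items):
        stim = [c for _, c in items if c is not None]
        c2 = sum(1 for c in stim if c == "case2")
        return len(items), c2, (c2 / len(stim) if stim else None)

    ft, fc2, fr = counts(first)
    st, sc2, sr = counts(second)
    return HalfSessionCounts(ft, st, fc2, sc2, fr, sr)
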