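"""Core domain types shared by every pipeline stage.

Time convention
---------------
All times are seconds from the start of the recording, real valued.  Every
interval in the package is half-open, ``[start_s, end_s)``: a sample at the
end time belongs to the next segment.  Sample ``i`` of a recording covers
``[i / rate, (i + 1) / rate)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Genotype",
    "Subject",
    "EEGRecording",
    "EventInterval",
    "StimulusLog",
    "ValidationError",
    "GENOTYPE_LABELS",
    "STATES",
]

#: Vigilance states used throughout (generator ground truth only).
STATES = ("awake", "nrem", "rem")

GENOTYPE_LABELS = {"hom_ko": "-/-", "het": "+/-", "wt": "+/+"}
_GENOTYPES = tuple(GENOTYPE_LABELS)
_TREATMENTS = ("none", "vpa")
_SEXES = ("m", "f", "unknown")


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates an invariant."""


@dataclass(frozen=True)
class Subject:
    """Animal metadata attached to a recording.

    ``genotype`` uses internal codes (``hom_ko``/``het``/``wt``); the
    conventional renderings ``-/-``, ``+/-``, ``+/+`` are available through
    :attr:`genotype_label`.
    """

    id: str = "subject"
    genotype: str = "wt"
    age_months: float = 3.0
    treatment: str = "none"
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if self.genotype not in _GENOTYPES:
            raise ValidationError(f"genotype must be one of {_GENOTYPES}, got {self.genotype!r}")
        if self.treatment not in _TREATMENTS:
            raise ValidationError(f"treatment must be one of {_TREATMENTS}, got {self.treatment!r}")
        if self.sex not in _SEXES:
            raise ValidationError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if not self.age_months > 0:
            raise ValidationError(f"age_months must be positive, got {self.age_months}")

    @property
    def genotype_label(self) -> str:
        return GENOTYPE_LABELS[self.genotype]


@dataclass
class EEGRecording:
    """A single-channel EEG voltage trace in microvolts.

    Parameters
    ----------
    samples
        Finite voltage samples (µV).
    sampling_rate_hz
        Sampling rate; chronic rodent EEG here is nominally 1 kHz.
    state_labels
        Optional per-epoch vigilance labels (generator ground truth); when
        present they must tile the full duration in ``epoch_length_s`` steps.
    """

    samples: np.ndarray
    sampling_rate_hz: float = 1000.0
    subject: Subject = field(default_factory=Subject)
    start_offset_s: float = 0.0
    state_labels: Optional[np.ndarray] = None
    epoch_length_s: Optional[float] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValidationError("samples must be a 1-D array")
        if not self.sampling_rate_hz > 0:
            raise ValidationError("sampling_rate_hz must be positive")
        bad = ~np.isfinite(self.samples)
        if bad.any():
            idx = int(np.argmax(bad))
            raise ValidationError(f"non-finite sample at index {idx}")
        if self.state_labels is not None:
            if self.epoch_length_s is None or not self.epoch_length_s > 0:
                raise ValidationError("state_labels require a positive epoch_length_s")
            self.state_labels = np.asarray(self.state_labels, dtype=object)
            unknown = set(self.state_labels) - set(STATES)
            if unknown:
                raise ValidationError(f"unknown vigilance labels: {sorted(unknown)}")
            n_needed = math.ceil(self.duration_s / self.epoch_length_s - 1e-9)
            if len(self.state_labels) < n_needed:
                raise ValidationError(
                    f"state labels cover {len(self.state_labels)} epochs, "
                    f"recording needs {n_needed}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def duration_h(self) -> float:
        return self.duration_s / 3600.0

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz

    def index_range(self, start_s: float, end_s: float) -> tuple[int, int]:
        """Sample index range ``[i0, i1)`` covered by ``[start_s, end_s)``.

        Sample ``i`` lives at time ``i / rate``; a tiny tolerance absorbs
        float rounding so that e.g. ``start_s = k / rate`` includes sample k.
        """
        rate = self.sampling_rate_hz
        i0 = int(math.ceil(start_s * rate - 1e-9))
        i1 = int(math.ceil(end_s * rate - 1e-9))
        return max(i0, 0), min(max(i1, 0), self.n_samples)

    def segment(self, start_s: float, end_s: float) -> np.ndarray:
        """Samples whose time stamps fall inside ``[start_s, end_s)``."""
        i0, i1 = self.index_range(start_s, end_s)
        return self.samples[i0:i1]

    def with_samples(self, samples: np.ndarray, sampling_rate_hz: Optional[float] = None) -> "EEGRecording":
        """Copy of this recording with replaced samples (and rate)."""
        return replace(
            self,
            samples=samples,
            sampling_rate_hz=sampling_rate_hz or self.sampling_rate_hz,
        )

    def state_intervals(self, state: str) -> list["EventInterval"]:
        """Ground-truth intervals (merged across consecutive epochs) for a state."""
        if self.state_labels is None:
            raise ValidationError("recording carries no state labels")
        out: list[EventInterval] = []
        e = float(self.epoch_length_s)  # type: ignore[arg-type]
        run_start = None
        for i, lab in enumerate(self.state_labels):
            if lab == state and run_start is None:
                run_start = i * e
            elif lab != state and run_start is not None:
                out.append(EventInterval(run_start, i * e, label=state))
                run_start = None
        if run_start is not None:
            out.append(EventInterval(run_start, min(len(self.state_labels) * e, self.duration_s), label=state))
        return out


@dataclass(frozen=True)
class EventInterval:
    """Half-open time interval ``[start_s, end_s)`` relative to recording start."""

    start_s: float
    end_s: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValidationError(f"end_s must exceed start_s, got [{self.start_s}, {self.end_s})")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)

    def overlap_s(self, other: "EventInterval") -> float:
        return max(0.0, min(self.end_s, other.end_s) - max(self.start_s, other.start_s))

    def shifted(self, offset_s: float) -> "EventInterval":
        return EventInterval(self.start_s + offset_s, self.end_s + offset_s, self.label)


def check_sorted_nonoverlapping(intervals: Sequence) -> None:
    """Raise ``ValidationError`` naming the first offending pair on overlap.

    Accepts anything with ``start_s``/``end_s`` attributes; touching
    intervals (``end == next start``) are allowed under the half-open
    convention.
    """
    for i in range(len(intervals) - 1):
        a, b = intervals[i], intervals[i + 1]
        if b.start_s < a.start_s or b.start_s < a.end_s - 1e-9:
            raise ValidationError(f"intervals {i} and {i + 1} overlap or are unsorted")


@dataclass
class StimulusLog:
    """Acoustic-stimulus onsets (buzzer tones delivered during live monitoring)."""

    onsets_s: np.ndarray
    tone_freq_hz: float = 2000.0
    level_db: float = 82.0

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        if self.onsets_s.ndim != 1:
            raise ValidationError("onsets_s must be 1-D")
        d = np.diff(self.onsets_s)
        if (d == 0).any():
            raise ValidationError("duplicate stimulus onsets")
        if (d < 0).any():
            raise ValidationError("stimulus onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onsets_s)
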