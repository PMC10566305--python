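"""Readers and writers for recordings, event tables, stimulus logs and configs.

Formats: EDF or two-column CSV (``time_s, amplitude_uv``) for recordings;
plain CSV for events and stimulus logs; YAML for configuration files.  All
writer/reader pairs round-trip (EDF within 16-bit quantization, text
exactly).
"""

from __future__ import annotations

import dataclasses
import os
import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import _edf
from .events import SWDEvent
from .types import (
    EEGRecording,
    EventInterval,
    StimulusLog,
    Subject,
    ValidationError,
    check_sorted_nonoverlapping,
)

__all__ = [
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "read_stimulus_log",
    "write_stimulus_log",
    "load_config",
    "save_config",
]

EVENT_COLUMNS = [
    "start_s",
    "end_s",
    "label",
    "duration_s",
    "dominant_freq_hz",
    "harmonic_ratio",
    "mean_band_power",
]


def _infer_format(path: Union[str, Path], format: Optional[str]) -> str:
    if format is not None:
        return format
    suffix = Path(path).suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in (".csv", ".txt", ".tsv"):
        return "csv"
    raise ValidationError(f"cannot infer recording format from {path!r}; pass format=")


def read_recording(
    path: Union[str, Path],
    format: Optional[str] = None,
    rate_hz: Optional[float] = None,
    subject: Optional[Subject] = None,
) -> EEGRecording:
    """Read a recording from EDF or CSV.

    CSV accepts either two columns (``time_s``, ``amplitude_uv``) — the rate
    is inferred from the time grid, which must be uniform within 1 ppm — or a
    single ``amplitude_uv`` column plus a declared ``rate_hz``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "edf":
        return _read_edf(path, subject=subject)
    if fmt != "csv":
        raise ValidationError(f"unknown recording format {fmt!r}")

    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" in df.columns and "amplitude_uv" in df.columns:
        t = df["time_s"].to_numpy(dtype=float)
        bad_t = ~np.isfinite(t)
        if bad_t.any():
            raise ValidationError(f"non-finite time at index {int(np.argmax(bad_t))}")
        dt = np.diff(t)
        if len(dt) == 0:
            raise ValidationError("recording needs at least two samples")
        mean_dt = float(np.mean(dt))
        if mean_dt <= 0 or np.max(np.abs(dt - mean_dt)) > 1e-6 * mean_dt + 1e-12:
            raise ValidationError("time grid is not uniform within 1 ppm")
        rate = 1.0 / mean_dt
        x = df["amplitude_uv"].to_numpy(dtype=float)
        offset = float(t[0])
    elif "amplitude_uv" in df.columns or df.shape[1] == 1:
        if rate_hz is None:
            raise ValidationError("single-column CSV needs a declared rate_hz")
        col = "amplitude_uv" if "amplitude_uv" in df.columns else df.columns[0]
        x = df[col].to_numpy(dtype=float)
        rate = float(rate_hz)
        offset = 0.0
    else:
        raise ValidationError("CSV must have (time_s, amplitude_uv) or a single amplitude column")
    return EEGRecording(
        samples=x,
        sampling_rate_hz=rate,
        subject=subject or Subject(),
        start_offset_s=offset,
    )


def _read_edf(path: Path, subject: Optional[Subject] = None) -> EEGRecording:
    import mne  # deferred: heavy import

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(os.fspath(path), preload=True, verbose="error")
    data = raw.get_data()[0] * 1e6  # mne returns volts
    return EEGRecording(
        samples=data,
        sampling_rate_hz=float(raw.info["sfreq"]),
        subject=subject or Subject(),
    )


def write_recording(rec: EEGRecording, path: Union[str, Path], format: Optional[str] = None) -> None:
    """Write a recording as EDF (16-bit) or CSV (``time_s, amplitude_uv``)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "edf":
        _edf.write_edf(
            os.fspath(path),
            rec.samples,
            rec.sampling_rate_hz,
            patient_id=rec.subject.id,
        )
    elif fmt == "csv":
        df = pd.DataFrame({"time_s": rec.times_s + rec.start_offset_s, "amplitude_uv": rec.samples})
        df.to_csv(path, index=False)
    else:
        raise ValidationError(f"unknown recording format {fmt!r}")


def write_events(events: Sequence[Union[EventInterval, SWDEvent]], path: Union[str, Path]) -> None:
    """Write events as a CSV table; refuses unsorted/overlapping input.

    Plain :class:`EventInterval` rows leave the spectral-metric columns
    empty; :class:`SWDEvent` rows fill them.
    """
    check_sorted_nonoverlapping([_as_interval(e) for e in events])
    rows = []
    for e in events:
        iv = _as_interval(e)
        row = {
            "start_s": iv.start_s,
            "end_s": iv.end_s,
            "label": iv.label,
            "duration_s": iv.duration_s,
            "dominant_freq_hz": "",
            "harmonic_ratio": "",
            "mean_band_power": "",
        }
        if isinstance(e, SWDEvent):
            row["dominant_freq_hz"] = e.dominant_freq_hz if e.dominant_freq_hz is not None else ""
            row["harmonic_ratio"] = e.harmonic_ratio if e.harmonic_ratio is not None else ""
            row["mean_band_power"] = e.mean_band_power if e.mean_band_power is not None else ""
        rows.append(row)
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    df.to_csv(path, index=False)


def _as_interval(e: Union[EventInterval, SWDEvent]) -> EventInterval:
    return e.interval if isinstance(e, SWDEvent) else e


def read_events(path: Union[str, Path]) -> list[Union[EventInterval, SWDEvent]]:
    """Read an event table written by :func:`write_events`."""
    df = pd.read_csv(path, float_precision="round_trip")
    out: list[Union[EventInterval, SWDEvent]] = []
    for _, row in df.iterrows():
        label = "" if pd.isna(row.get("label", "")) else str(row.get("label", ""))
        iv = EventInterval(float(row["start_s"]), float(row["end_s"]), label)
        metrics = {}
        for col in ("dominant_freq_hz", "harmonic_ratio", "mean_band_power"):
            v = row.get(col)
            metrics[col] = None if v is None or (isinstance(v, float) and np.isnan(v)) or v == "" else float(v)
        if any(v is not None for v in metrics.values()):
            out.append(SWDEvent(interval=iv, **metrics))
        else:
            out.append(iv)
    return out


def read_stimulus_log(path: Union[str, Path]) -> StimulusLog:
    """Read stimulus onsets from a CSV with an ``onset_s`` column.

    Unsorted input is sorted with a warning; duplicate onsets are an error.
    An empty file yields an empty log.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return StimulusLog(onsets_s=np.array([]))
    if len(df) == 0:
        return StimulusLog(onsets_s=np.array([]))
    col = "onset_s" if "onset_s" in df.columns else df.columns[0]
    onsets = df[col].to_numpy(dtype=float)
    if (np.diff(onsets) == 0).any():
        raise ValidationError("duplicate stimulus onsets")
    if not np.all(np.diff(onsets) > 0):
        warnings.warn("stimulus onsets were not sorted; sorting", stacklevel=2)
        onsets = np.sort(onsets)
    kwargs = {}
    if "tone_freq_hz" in df.columns:
        kwargs["tone_freq_hz"] = float(df["tone_freq_hz"].iloc[0])
    if "level_db" in df.columns:
        kwargs["level_db"] = float(df["level_db"].iloc[0])
    return StimulusLog(onsets_s=onsets, **kwargs)


def write_stimulus_log(log: StimulusLog, path: Union[str, Path]) -> None:
    pd.DataFrame(
        {
            "onset_s": log.onsets_s,
            "tone_freq_hz": log.tone_freq_hz,
            "level_db": log.level_db,
        }
    ).to_csv(path, index=False)


def load_config(path: Union[str, Path]) -> dict:
    """Load a nestable key-value (YAML) config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def save_config(config, path: Union[str, Path]) -> None:
    """Write a dataclass (or dict) config as YAML."""
    data = dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
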