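"""Minimal standard-EDF (16-bit) writer for single-channel recordings.

Only plain EDF is produced (no EDF+ annotation channel), one signal,
physical dimension "uV".  Reading goes through :mod:`mne`, which serves as
an independent decoder of the files written here.  The final data record is
zero-padded, so read-back duration is rounded up to a whole record.
"""

from __future__ import annotations

import datetime as _dt
import math

import numpy as np

_MAX_RECORD_BYTES = 61440  # recommended EDF record payload limit


def _field(value: str, width: int) -> bytes:
    s = value[:width]
    return s.ljust(width).encode("ascii")


def _record_layout(n_samples: int, rate_hz: float) -> tuple[int, float]:
    """Choose (samples_per_record, record_duration_s)."""
    if n_samples * 2 <= _MAX_RECORD_BYTES:
        return n_samples, n_samples / rate_hz
    rate_int = int(round(rate_hz))
    if abs(rate_hz - rate_int) < 1e-6 and rate_int * 2 <= _MAX_RECORD_BYTES:
        return rate_int, rate_int / rate_hz
    # fall back: ~0.25 s records
    spr = max(1, min(int(rate_hz * 0.25), _MAX_RECORD_BYTES // 2))
    return spr, spr / rate_hz


def write_edf(
    path: str,
    samples_uv: np.ndarray,
    rate_hz: float,
    patient_id: str = "X",
    recording_id: str = "swdkit",
) -> None:
    x = np.asarray(samples_uv, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("samples must be a non-empty 1-D array")
    spr, rec_dur = _record_layout(len(x), rate_hz)
    n_records = math.ceil(len(x) / spr)

    phys_min = float(np.min(x))
    phys_max = float(np.max(x))
    if phys_max <= phys_min:  # constant signal; EDF needs a non-empty range
        phys_max = phys_min + 1.0
    dig_min, dig_max = -32768, 32767
    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((x - phys_min) * gain + dig_min).astype("<i2")
    pad = n_records * spr - len(x)
    if pad:
        zero_dig = int(np.clip(round((0.0 - phys_min) * gain + dig_min), dig_min, dig_max))
        digital = np.concatenate([digital, np.full(pad, zero_dig, dtype="<i2")])

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _field("0", 8),  # version
            _field(patient_id, 80),
            _field(recording_id, 80),
            _field(now.strftime("%d.%m.%y"), 8),
            _field(now.strftime("%H.%M.%S"), 8),
            _field(str(256 + 256), 8),  # header bytes: fixed + 1 signal
            _field("", 44),  # reserved
            _field(str(n_records), 8),
            _field(f"{rec_dur:.6f}"[:8], 8),
            _field("1", 4),  # number of signals
            # per-signal fields
            _field("EEG", 16),  # label
            _field("", 80),  # transducer
            _field("uV", 8),  # physical dimension
            _field(f"{phys_min:.8g}"[:8], 8),
            _field(f"{phys_max:.8g}"[:8], 8),
            _field(str(dig_min), 8),
            _field(str(dig_max), 8),
            _field("", 80),  # prefiltering
            _field(str(spr), 8),
            _field("", 32),  # reserved
        ]
    )
    assert len(header) == 512
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())
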