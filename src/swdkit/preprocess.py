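"""Signal conditioning before detection: high-pass filtering and resampling.

The high-pass removes DC and slow drift below 0.9 Hz before the wavelet
transform.  Zero-phase (forward-backward) filtering is used because event
boundary timing matters downstream; the 4th-order Butterworth design trades
rolloff against edge transients.
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .types import EEGRecording, ValidationError

__all__ = ["highpass", "resample"]


def highpass(rec: EEGRecording, cutoff_hz: float = 0.9, order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth high-pass (−3 dB at ``cutoff_hz``).

    Output length equals input length.  Warns when the recording is shorter
    than three filter time constants, where edge effects dominate.
    """
    nyq = rec.sampling_rate_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValidationError(f"cutoff_hz must be in (0, {nyq}), got {cutoff_hz}")
    tau = 1.0 / (2 * np.pi * cutoff_hz)
    if rec.duration_s < 3 * tau:
        warnings.warn(
            f"recording ({rec.duration_s:.2f} s) shorter than 3 filter time constants; "
            "edge effects dominate",
            stacklevel=2,
        )
    sos = sps.butter(order, cutoff_hz, btype="highpass", fs=rec.sampling_rate_hz, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.samples)
    return rec.with_samples(filtered)


def resample(rec: EEGRecording, target_rate_hz: float = 1000.0) -> EEGRecording:
    """Polyphase anti-aliased resampling to ``target_rate_hz``.

    Non-rational rate ratios are approximated by the nearest rational
    (denominator ≤ 1000) with a warning.  Duration is preserved within one
    output sample.
    """
    if not target_rate_hz > 0:
        raise ValidationError("target_rate_hz must be positive")
    if abs(target_rate_hz - rec.sampling_rate_hz) < 1e-9:
        return rec.with_samples(rec.samples.copy())
    ratio = Fraction(target_rate_hz / rec.sampling_rate_hz).limit_denominator(1000)
    achieved = rec.sampling_rate_hz * ratio
    if abs(achieved - target_rate_hz) > 1e-6 * target_rate_hz:
        warnings.warn(
            f"non-rational resampling ratio; using {ratio} "
            f"(achieved rate {float(achieved):.6f} Hz)",
            stacklevel=2,
        )
    up, down = ratio.numerator, ratio.denominator
    out = sps.resample_poly(rec.samples, up, down)
    return rec.with_samples(out, sampling_rate_hz=float(achieved))
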