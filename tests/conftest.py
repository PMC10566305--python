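"""Shared fixtures: small synthetic sessions reused across test modules."""

import numpy as np
import pytest

from swdkit.detect import DetectorConfig, detect_swd
from swdkit.simulate import GeneratorConfig, generate_session
from swdkit.types import EEGRecording, Subject


@pytest.fixture(scope="session")
def ko_session():
    """15-minute knockout-style session with ground truth (seed fixed)."""
    return generate_session("ko", 0.25, seed=1)


@pytest.fixture(scope="session")
def ko_detection(ko_session):
    """Detected events + report for the shared session."""
    events, report = detect_swd(ko_session.recording, return_report=True)
    return events, report


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture()
def detector_config():
    return DetectorConfig()


def make_recording(samples, rate=1000.0, **kw):
    return EEGRecording(samples=np.asarray(samples, dtype=float), sampling_rate_hz=rate, **kw)


@pytest.fixture()
def sine_recording():
    """10 s of a unit 8 Hz sinusoid at 1 kHz."""
    t = np.arange(0, 10, 1e-3)
    return make_recording(np.sin(2 * np.pi * 8 * t))
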