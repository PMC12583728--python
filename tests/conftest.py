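import numpy as np
import pytest

from thermobuzz.synthetic import (BuzzSpec, RecordingPlan, default_recording_plan,
                                  synthesize_recording)


@pytest.fixture(scope="session")
def tone_plan():
    """One clean 2 s, 3-harmonic buzz at the grand-mean buzz frequency."""
    return RecordingPlan(
        buzzes=[BuzzSpec(onset_time=1.0, duration=2.0, f0=217.0, peak_accel=100.0)],
        total_duration=5.0, noise_sd=0.0, seed=0,
    )


@pytest.fixture(scope="session")
def tone_recording(tone_plan):
    return synthesize_recording(tone_plan)


@pytest.fixture(scope="session")
def matched_plan():
    """Buzzes of comparable amplitude and moderate length.

    With a threshold relative to the recording-wide envelope maximum, the
    onset-detection delay on an attack ramp scales with the amplitude
    ratio, so amplitude-matched buzzes are the regime where +/-25 ms
    onset agreement is well defined.
    """
    return default_recording_plan(
        seed=11, n_buzzes=6, duration_range=(0.15, 1.0),
        peak_range=(100.0, 300.0), noise_sd=0.5,
    )


@pytest.fixture(scope="session")
def matched_recording(matched_plan):
    return synthesize_recording(matched_plan)
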