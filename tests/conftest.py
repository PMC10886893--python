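import numpy as np
import pandas as pd
import pytest

from motioncue.montage import CHANNEL_LABELS
from motioncue.protocol import ProtocolConfig
from motioncue.synth import EncodingProfile, SessionRecording, SynthConfig, generate_session


@pytest.fixture(scope="session")
def short_protocol() -> ProtocolConfig:
    """One session of 11 trials (one per speed): cheap signal-chain fixture."""
    return ProtocolConfig(sessions_per_condition=1, trials_per_speed_per_session=1)


@pytest.fixture(scope="session")
def default_session():
    """One full-protocol session (33 trials) under the eye-fixed condition."""
    cfg = SynthConfig(seed=42)
    return generate_session(cfg, "eye_fixed", 42)


@pytest.fixture(scope="session")
def tracking_session():
    cfg = SynthConfig(seed=43)
    return generate_session(cfg, "eye_tracking", 43)


@pytest.fixture(scope="session")
def blink_session(short_protocol):
    """Short session with frequent intertrial blinks and no cue encoding."""
    cfg = SynthConfig(
        protocol=short_protocol,
        profiles={lab: EncodingProfile(electrode_label=lab) for lab in CHANNEL_LABELS},
        blink_rate_hz=1.0,
        seed=7,
    )
    return generate_session(cfg, "eye_fixed", 7)


def make_recording(data: np.ndarray, labels=None, fs: float = 500.0) -> SessionRecording:
    """Bare recording around a raw matrix, for unit tests of single stages."""
    data = np.asarray(data, dtype=float)
    n_ch, n_samp = data.shape
    labels = labels or CHANNEL_LABELS[:n_ch]
    events = pd.DataFrame({"sample": [0], "trial_id": [0], "kind": ["fixation_on"]})
    gaze = np.full((n_samp, 2), 0.5)
    return SessionRecording(
        data=data, channel_labels=list(labels), events=events,
        gaze=gaze, condition="eye_fixed", sample_rate_hz=fs,
    )
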