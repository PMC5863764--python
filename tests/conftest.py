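"""Shared fixtures: small synthetic recordings and hand-built epoch sets."""

import numpy as np
import pandas as pd
import pytest

from naplab import SimConfig, generate_recording
from naplab.io_core import EpochSet


def make_epochs(data, fs=200.0, tmin=-1.0, conditions=None, adjectives=None,
                rounds=None, channel_labels=None, onsets=None):
    """Build an EpochSet from a (trials, channels, time) array."""
    data = np.asarray(data, float)
    n, n_ch, n_t = data.shape
    times = tmin + np.arange(n_t) / fs
    meta = pd.DataFrame({
        "onset_s": onsets if onsets is not None else 10.0 + 8.0 * np.arange(n),
        "condition": conditions if conditions is not None else ["old-object"] * n,
        "category": [c.split("-")[-1] if c != "control" else "control"
                     for c in (conditions or ["old-object"] * n)],
        "adjective_id": adjectives if adjectives is not None else np.arange(n),
        "round": rounds if rounds is not None else np.zeros(n, int),
    })
    labels = list(channel_labels) if channel_labels is not None else \
        [f"ch{i}" for i in range(n_ch)]
    return EpochSet(data=data, times=times, sampling_rate=fs,
                    channel_labels=labels, metadata=meta)


@pytest.fixture(scope="session")
def short_recording():
    """A 5-minute default-condition recording with cues and ground truth."""
    cfg = SimConfig(duration=300.0, seed=123, n_adjectives_per_category=4,
                    n_rounds=2)
    return generate_recording(cfg, subject=0)


@pytest.fixture(scope="session")
def quiet_recording():
    """A cue-free recording with only background SOs and spindles."""
    cfg = SimConfig(duration=300.0, seed=7, n_rounds=0,
                    category_pattern_snr=0.0)
    return generate_recording(cfg, subject=0)
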