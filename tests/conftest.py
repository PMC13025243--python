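import numpy as np
import pandas as pd
import pytest

from eegti import Recording, StudySimSpec


@pytest.fixture
def tone_recording():
    """Factory for single- or multi-tone test recordings."""

    def make(freq=10.0, amplitude=2.0, duration_s=60.0, fs=250.0,
             n_channels=1, subject="s00", condition="prayer"):
        t = np.arange(int(round(duration_s * fs))) / fs
        x = amplitude * np.sin(2 * np.pi * freq * t)
        samples = np.tile(x, (n_channels, 1))
        labels = tuple(f"ch{i:02d}" for i in range(n_channels))
        return Recording(subject, condition, fs, labels, samples)

    return make


@pytest.fixture
def tiny_spec():
    """A fast study: 2 subjects, 2 channels, 60-s blocks (30 epochs)."""
    return StudySimSpec(n_subjects=2, n_channels=2, block_s=60.0, seed=7)


@pytest.fixture
def pseudo_subject_powers():
    """One pseudo-subject carrying the group-mean band powers of the study."""
    powers = {
        "delta": 9327.87,
        "theta": 3849.94,
        "alpha_low": 5469.42,
        "alpha_high": 4729.73,
        "beta_low": 2109.69,
        "beta_high": 1415.47,
        "gamma_low": 943.36,
        "gamma_high": 478.68,
    }
    return pd.DataFrame(
        [
            {"subject": "mean", "condition": "pooled", "channel": "pooled",
             "band": band, "power_uv2": p}
            for band, p in powers.items()
        ]
    )
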