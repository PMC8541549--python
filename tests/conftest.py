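"""Shared fixtures: small simulated sessions with known ground truth."""

import numpy as np
import pytest

from eegcompare.recording import Recording
from eegcompare.synthetic import SimConfig, simulate_subject


@pytest.fixture(scope="session")
def reduced_config() -> SimConfig:
    """Down-scaled study conditions (fewer trials, 256 Hz)."""
    return SimConfig(seed=1234).reduced()


@pytest.fixture(scope="session")
def clean_config() -> SimConfig:
    """Noise-free configuration: only the deterministic evoked content."""
    return SimConfig(seed=7, pink_noise_sd=0.0, white_noise_sd=0.0,
                     delta_noise_sd=0.0, drift_sd_dry=0.0, drift_sd_gel=0.0,
                     line_noise_amp=0.0, blink_rate=0.0,
                     p_bad_channel_dry=0.0, p_bad_channel_gel=0.0,
                     amplitude_cv=0.0, latency_jitter_sd=0.0).reduced()


@pytest.fixture(scope="session")
def dry_session(reduced_config):
    recs, gt = simulate_subject(reduced_config, 0, "dry")
    return recs, gt


@pytest.fixture(scope="session")
def gel_session(reduced_config):
    recs, gt = simulate_subject(reduced_config, 0, "gel")
    return recs, gt


def make_recording(data, sample_rate=256.0, labels=None, **kw) -> Recording:
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if labels is None:
        labels = [f"C{i + 1}" for i in range(data.shape[0])]
    return Recording(data=data, sample_rate=sample_rate,
                     channel_labels=labels, **kw)
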