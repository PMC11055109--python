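import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

from eegfatigue.recording import Epoch
from eegfatigue.simulate import ScenarioConfig, identification_scenario, simulate_eeg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_epoch(x, fs=128.0, start_min=0.0):
    return Epoch(samples=x, sampling_rate=fs, start_min=start_min, duration_s=len(x) / fs)


def sine_epoch(freq_hz, amp=1.0, fs=128.0, duration_s=60.0, start_min=0.0):
    t = np.arange(int(duration_s * fs)) / fs
    return make_epoch(amp * np.sin(2 * np.pi * freq_hz * t), fs=fs, start_min=start_min)


@pytest.fixture
def stationary_alpha_config():
    """Alpha-only unit-amplitude stationary scenario, noise-free."""
    return identification_scenario(
        band_envelopes={"alpha": [(0.0, 1.0)]},
        noise_sd=0.0,
        minute_amp_sd=0.0,
        duration_min=1.0,
        n_subjects=2,
    )


@pytest.fixture
def short_fatigue_config():
    """Beta halves over 30 min, alpha constant; deterministic envelopes."""
    return identification_scenario(
        band_envelopes={"alpha": [(0.0, 1.0)], "beta": [(0.0, 1.0), (30.0, 0.5)]},
        noise_sd=0.0,
        minute_amp_sd=0.0,
        n_subjects=2,
    )
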