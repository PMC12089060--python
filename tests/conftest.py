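import numpy as np
import pytest

from eegadvdenoise.pipeline import build_pairs, smoke_config, split_pairs
from eegadvdenoise.synthetic import simulate_clean_eeg


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def clean_recording():
    """A 3-channel, 30 s clean surrogate at 128 Hz."""
    return simulate_clean_eeg(n_channels=3, n_samples=30 * 128, sample_rate=128.0, seed=42)


@pytest.fixture(scope="session")
def smoke_pairs():
    """The standard reduced fixture: 1 channel, ~200 pairs, L=64, white 0 dB."""
    cfg = smoke_config(seed=1)
    pairs = build_pairs(cfg)
    train, test = split_pairs(pairs, cfg.test_fraction, cfg.split_seed)
    return cfg, train, test
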