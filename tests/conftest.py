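import sys
from pathlib import Path

import numpy as np
import pytest

from freezeindex import Signal

sys.path.insert(0, str(Path(__file__).parent))  # make the oracle helpers importable


@pytest.fixture
def rng():
    return np.random.default_rng(20250926)


@pytest.fixture
def short_noise_signal(rng):
    """8 s of unit white noise at 64 Hz — small enough for brute-force oracles."""
    return Signal(samples=rng.standard_normal(8 * 64), fs=64.0)


@pytest.fixture
def two_tone_signal():
    """Equal-amplitude 1 Hz + 5 Hz tones at 100 Hz: power in both bands."""
    t = np.arange(1000) / 100.0
    return Signal(samples=np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 5.0 * t), fs=100.0)
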