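import numpy as np
import pytest

from sealscape.audio import AudioSegment

RATE = 22050.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone():
    """30 s, 500 Hz unit sine at 11025 Hz."""
    rate = 11025.0
    t = np.arange(int(30 * rate)) / rate
    return AudioSegment(np.sin(2 * np.pi * 500 * t), rate)


def make_tone(freq, dur, rate=RATE, amp=1.0):
    t = np.arange(int(dur * rate)) / rate
    return AudioSegment(amp * np.sin(2 * np.pi * freq * t), rate)


@pytest.fixture
def white_noise(rng):
    return AudioSegment(rng.standard_normal(int(20 * RATE)), RATE)
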