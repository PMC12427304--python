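import numpy as np
import pytest

from pigvox.audio_io import AudioSegment


@pytest.fixture
def rate():
    return 48_000.0


@pytest.fixture
def sine_factory(rate):
    def make(freq, amplitude=1.0, duration=1.0, fs=None, phase=0.0):
        fs = fs or rate
        t = np.arange(int(round(duration * fs))) / fs
        return AudioSegment(amplitude * np.sin(2 * np.pi * freq * t + phase), fs)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def flat_band_noise(rng, rate, duration, f_hi):
    """Noise with exactly flat power in (0, f_hi] and none above."""
    n = int(round(duration * rate))
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    mag = ((freqs > 0) & (freqs <= f_hi)).astype(float)
    phases = rng.uniform(0, 2 * np.pi, freqs.size)
    spectrum = mag * np.exp(1j * phases)
    x = np.fft.irfft(spectrum, n)
    return AudioSegment(0.5 * x / np.max(np.abs(x)), rate)


@pytest.fixture
def small_session_config():
    """A quick session for pipeline mechanics (not the study layout)."""
    from pigvox.synth import SessionConfig

    return SessionConfig(
        rate=16_000.0,
        total_duration=60.0,
        event_counts={"grunting": 4, "fight": 3, "alert": 2, "sneezing": 2},
        annotation_jitter=0.5,
        min_gap=1.5,
        seed=7,
    )
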