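import numpy as np
import pytest

from somnohrv.preprocess import Tachogram
from somnohrv.synth import NightSpec, generate_night


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


@pytest.fixture(scope="session")
def short_night():
    """One 120-min synthetic night with 10 min sleep-onset latency."""
    return generate_night(NightSpec(duration_min=120, onset_latency_min=10), seed=314)


def make_tone_tachogram(
    freqs_amps, duration_s=600.0, grid_rate=4.0, mean=900.0, noise_sd=0.0, seed=0
):
    """Uniform tachogram holding pure tones (+ optional white noise)."""
    t = np.arange(0.0, duration_s, 1.0 / grid_rate)
    x = np.full(t.size, float(mean))
    for f, a in freqs_amps:
        x += a * np.sin(2.0 * np.pi * f * t)
    if noise_sd > 0:
        x += np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
    return Tachogram(x, np.ones(t.size, dtype=bool), grid_rate)
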