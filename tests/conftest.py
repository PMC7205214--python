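import numpy as np
import pytest

from retipulse.harmonic import CycleTiming


@pytest.fixture
def timing70():
    """Three cardiac cycles totalling 70 frames (typical recording)."""
    return CycleTiming((23, 24, 23))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def snr_noise_sd(signal, snr):
    """Noise sd giving the requested RMS signal-to-noise ratio."""
    signal = np.asarray(signal, dtype=float)
    return float(signal.std() / snr)


def make_ar1(rng, n, rho, sd):
    """Stationary AR(1) noise with marginal sd, for test signal synthesis."""
    e = np.empty(n)
    e[0] = rng.normal(0, sd)
    innov = sd * np.sqrt(1 - rho * rho)
    for k in range(1, n):
        e[k] = rho * e[k - 1] + rng.normal(0, innov)
    return e
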