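import numpy as np
import pytest

from pabst.synthetic import NoiseSpec, OscillatorSpec, generate_lfp
from pabst.types import band_4hz, band_20hz


@pytest.fixture(scope="session")
def noiseless_4hz():
    """30 s of a pure 4 Hz oscillation at 1 kHz, with ground-truth phase."""
    return generate_lfp([OscillatorSpec(4.0)], NoiseSpec(1.0, 0.0), 30.0, 1000.0, seed=0)


@pytest.fixture(scope="session")
def noisy_4hz():
    """60 s of a jittered 4 Hz oscillator in 1/f noise at amplitude-SNR 2."""
    osc = OscillatorSpec(4.0, amplitude=1.0, frequency_jitter_sd=0.3)
    return generate_lfp([osc], NoiseSpec(1.0, 0.5), 60.0, 1000.0, seed=1)


@pytest.fixture(scope="session")
def band4():
    return band_4hz()


@pytest.fixture(scope="session")
def band20():
    return band_20hz()
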