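import math

import numpy as np
import pytest

from fbccnn.epochs import StimulusLayout
from fbccnn.synth import SynthConfig, generate_epochs, make_layout


@pytest.fixture(scope="session")
def nakanishi_layout():
    return make_layout("nakanishi12")


@pytest.fixture(scope="session")
def benchmark_layout():
    return make_layout("benchmark40")


@pytest.fixture(scope="session")
def noiseless_epochs(nakanishi_layout):
    """One noiseless block of 12-target epochs at 256 Hz, 4 s."""
    cfg = SynthConfig(n_blocks=1, snr_db=math.inf, seed=11)
    return generate_epochs(nakanishi_layout, 256.0, cfg)


@pytest.fixture(scope="session")
def noisy_epochs(nakanishi_layout):
    """Six blocks at 10 dB SNR — enough for small training runs."""
    cfg = SynthConfig(n_blocks=6, snr_db=10.0, seed=9)
    return generate_epochs(nakanishi_layout, 256.0, cfg)


@pytest.fixture(scope="session")
def tiny_layout():
    """Four well-separated targets for fast unit tests."""
    return StimulusLayout(n_targets=4, f0=9.0, delta_f=2.0, phi0=0.0,
                          delta_phi=0.5 * math.pi)
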