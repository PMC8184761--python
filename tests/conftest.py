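import numpy as np
import pytest

from respectra.chem import Peptide
from respectra.simulate import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def peptide():
    return Peptide("PEPTIDEK", (), 2)


@pytest.fixture
def noiseless_cfg():
    """Study conditions with every noise source switched off (oracle limit)."""
    return SimConfig(seed=5, ppm_jitter=0.0, noise_per_100th=0.0,
                     intensity_sigma=0.0)


@pytest.fixture
def noisy_cfg():
    return SimConfig(seed=5)
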