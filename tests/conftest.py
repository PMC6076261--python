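import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from punctaflux import synthgen


@pytest.fixture(scope="session")
def hcs_field_clean():
    """A noiseless default-geometry HCS field with its ground truth."""
    spec = synthgen.FieldSpec(seed=11, noise_gaussian_sd=0.0,
                              noise_poisson=False, background_gradient=0.0,
                              brightness_lognorm_sd=0.0)
    return synthgen.gen_hcs_field(spec), spec


@pytest.fixture(scope="session")
def hcs_field_noisy():
    """A default-SNR HCS field with its ground truth."""
    spec = synthgen.FieldSpec(seed=7)
    return synthgen.gen_hcs_field(spec), spec


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
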