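import numpy as np
import pytest

from omsas.preprocess import BinaryMask, GrayscaleSlice, PreprocessConfig, \
    preprocess_sample
from omsas.synthetic_data import easy_params, generate_phantom


@pytest.fixture(scope="session")
def phantom_pair():
    """One deterministic easy phantom (raw slice + mask)."""
    slc, mask, pid = generate_phantom(easy_params(seed=7), 0)
    return slc, mask


@pytest.fixture(scope="session")
def processed_64(phantom_pair):
    """The phantom preprocessed to the 64x64 network input size."""
    slc, mask = phantom_pair
    return preprocess_sample(slc, mask, PreprocessConfig(target_size=(64, 64)))


@pytest.fixture(scope="session")
def asymmetric_image():
    """A small image with no dihedral symmetry (all 8 orbit copies differ)."""
    return np.arange(16, dtype=float).reshape(4, 4)
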