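import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_synth():
    """Small 4-class synthetic pool at side 32, shared across tests."""
    from leafrgn.data_io import synth_generate
    images, labels, names, unlabeled = synth_generate(
        12, seed=7, side=32, n_unlabeled=8)
    return images, labels, names, unlabeled
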