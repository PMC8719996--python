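import numpy as np
import pytest

from obstruseg import phantoms as ph


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def clean_pairs():
    """Small noise-free phantom set, one per class."""
    return ph.make_phantom_set(1, template_overrides={"noise_sd": 0.0}, seed=5, height=64, width=64)


@pytest.fixture(scope="session")
def noisy_pairs():
    return ph.make_phantom_set(2, seed=9, height=64, width=64, noise_sd=0.05)


@pytest.fixture(scope="session")
def toy_xy():
    """Four-point linearly separable 2-class set."""
    X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
    y = np.array([0, 0, 1, 1])
    return X, y
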