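import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mvkmeans as mk

settings.register_profile(
    "default",
    deadline=None,
    max_examples=30,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_view_blobs():
    """Two small aligned views with three well-separated clusters."""
    gen = np.random.default_rng(7)
    centers1 = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    centers2 = np.array([[5.0], [-5.0], [15.0]])
    labels = np.repeat([0, 1, 2], 20)
    X1 = centers1[labels] + 0.3 * gen.standard_normal((60, 2))
    X2 = centers2[labels] + 0.3 * gen.standard_normal((60, 1))
    return mk.MultiViewDataset(views=[X1, X2], labels=labels)


@pytest.fixture(scope="session")
def high_sep_dataset():
    """One frozen draw of the default high-separation study conditions."""
    return mk.generate(mk.default_class_profiles("high", n=800, seed=11)).dataset
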