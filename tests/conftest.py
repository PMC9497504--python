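import numpy as np
import pytest

from asymcl.contrastive import FeatureBatch, l2_normalize


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture
def three_sample_batch():
    """The worked fixture: z1 = z2 = (1,0), z3 = (0,1), labels A,A,B."""
    Z = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    return FeatureBatch(Z, np.array([0, 0, 1]))


def random_batch(rng, n=None, d=None, n_classes=2):
    """A random unit-norm batch with at least two samples."""
    n = n or int(rng.integers(2, 17))
    d = d or int(rng.integers(2, 33))
    Z = l2_normalize(rng.standard_normal((n, d)))
    y = rng.integers(0, n_classes, n)
    return FeatureBatch(Z, y)
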