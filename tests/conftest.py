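import numpy as np
import pytest

from ktgel import LabeledFeatureSet


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def blobs():
    """Two well-separated Gaussian blobs in 2-D, 200 samples."""
    g = np.random.default_rng(7)
    X = np.vstack([g.normal(0.0, 0.5, (100, 2)), g.normal(2.0, 0.5, (100, 2))])
    y = np.array([1] * 100 + [2] * 100)
    return LabeledFeatureSet(X, y)


@pytest.fixture
def three_class(rng):
    """Three linearly separable classes, 150 samples, 4 features."""
    centers = rng.uniform(-2, 2, (3, 4))
    X = np.vstack([c + rng.normal(0, 0.4, (50, 4)) for c in centers])
    y = np.repeat([1, 2, 3], 50)
    return LabeledFeatureSet(X, y)


@pytest.fixture
def tiny_instance():
    """n=2, L=3, 40-sample two-class instance used for exhaustive mask search."""
    g = np.random.default_rng(42)
    X = np.vstack([g.normal(0, 0.6, (20, 2)), g.normal(1.2, 0.6, (20, 2))])
    y = np.array([1] * 20 + [2] * 20)
    return LabeledFeatureSet(X, y)
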