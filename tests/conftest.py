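import numpy as np
import pytest

from chemconform.data import SamplingStrategy
from chemconform.synthetic import (
    SyntheticSpec,
    gen_numeric_classification,
    gen_numeric_regression,
    gen_toy_molecules,
)


@pytest.fixture(scope="session")
def gaussian_classification():
    """Balanced 2-class Gaussian mixture, 600 train rows."""
    return gen_numeric_classification(SyntheticSpec(n=600, seed=11))


@pytest.fixture(scope="session")
def gaussian_classification_test():
    return gen_numeric_classification(SyntheticSpec(n=400, seed=12))


@pytest.fixture(scope="session")
def linear_regression_data():
    return gen_numeric_regression(SyntheticSpec(task="regression", n=600, noise=0.5, seed=21))


@pytest.fixture(scope="session")
def toy_molecules():
    return gen_toy_molecules(60, seed=5)


@pytest.fixture()
def single_split():
    return SamplingStrategy(kind="random", calibration_ratio=0.2, n_splits=1, seed=7)


@pytest.fixture(scope="session")
def separable_toy():
    """Linearly separable 2-class toy set (20 points)."""
    rng = np.random.default_rng(0)
    X = rng.standard_normal((20, 2))
    y = np.where(X[:, 0] > 0, "pos", "neg")
    X[:, 0] += np.where(X[:, 0] > 0, 2.0, -2.0)
    return X, y
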