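import numpy as np
import pandas as pd
import pytest

from pfastox import (
    DescriptorMatrix,
    SyntheticSpec,
    ToxClass,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """100-compound two-class dataset with 3 informative + 10 noise features."""
    spec = SyntheticSpec(
        n_high=60, n_low=40, n_informative=3, n_noise=10,
        class_mean_shift=2.0, rho=0.0, seed=42,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def separable_dataset():
    """Well-separated dataset (shift 3 sd) for near-perfect classification."""
    spec = SyntheticSpec(
        n_high=90, n_low=60, n_informative=3, n_noise=5,
        class_mean_shift=3.0, rho=0.0, seed=7,
    )
    return generate_dataset(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(123)


def make_matrix(arr, ids=None, cols=None) -> DescriptorMatrix:
    arr = np.atleast_2d(np.asarray(arr, dtype=float))
    ids = ids or [f"c{i}" for i in range(arr.shape[0])]
    cols = cols or [f"f{j}" for j in range(arr.shape[1])]
    return DescriptorMatrix(pd.DataFrame(arr, index=ids, columns=cols))


@pytest.fixture
def matrix_factory():
    return make_matrix
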