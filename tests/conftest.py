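import logging

import numpy as np
import pandas as pd
import pytest

from multikernel import KernelSpec, compute_gram

logging.getLogger("multikernel").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_table():
    """Small numeric sample-by-feature table."""
    return pd.DataFrame(
        [[1.0, 2.0], [3.0, 4.0], [-1.0, 0.5], [0.0, -2.0]],
        index=["a", "b", "c", "d"],
        columns=["f1", "f2"],
    )


@pytest.fixture
def separable_1d():
    """Two symmetric points on a line: the textbook max-margin problem."""
    X = pd.DataFrame({"x": [-1.0, 1.0]}, index=["neg", "pos"])
    y = np.array([-1.0, 1.0])
    return X, y


def make_gaussian_toy(seed, n_per_class=20, gap=4.0, p=2, prefix="s"):
    """Two well-separated spherical Gaussian clusters."""
    rng = np.random.default_rng(seed)
    a = rng.normal(-gap / 2, 1.0, size=(n_per_class, p))
    b = rng.normal(+gap / 2, 1.0, size=(n_per_class, p))
    X = pd.DataFrame(
        np.vstack([a, b]),
        index=[f"{prefix}{i}" for i in range(2 * n_per_class)],
        columns=[f"f{j}" for j in range(p)],
    )
    y = np.r_[np.full(n_per_class, -1.0), np.full(n_per_class, 1.0)]
    return X, y


@pytest.fixture
def gaussian_toy():
    return make_gaussian_toy(0)


def random_psd_grams(rng, n=15, M=2):
    """Random PSD Gram matrices sharing ids."""
    ids = [f"s{i}" for i in range(n)]
    grams = []
    from multikernel import GramMatrix

    for _ in range(M):
        A = rng.normal(size=(n, n))
        grams.append(GramMatrix(A @ A.T / n, ids, ids, "combined"))
    return grams
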