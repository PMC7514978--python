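import numpy as np
import pytest

from targetbn.data import from_codes
from targetbn.info_theory import build_counts


@pytest.fixture
def toy_binary():
    """8-row binary X/C table with joint counts [[3,1],[1,3]]."""
    x = np.array([0, 0, 0, 0, 1, 1, 1, 1])[:, None]
    y = np.array([0, 0, 0, 1, 0, 1, 1, 1])
    return from_codes(x, y, [2])


@pytest.fixture
def toy_cache(toy_binary):
    return build_counts(toy_binary)


def random_dataset(rng, n=3, v=3, m=2, rows=40, missing=0.0):
    """Small random categorical dataset for property tests."""
    X = rng.integers(0, v, size=(rows, n))
    if missing:
        mask = rng.random((rows, n)) < missing
        X = np.where(mask, -1, X)
    y = rng.integers(0, m, size=rows)
    return from_codes(X, y, [v] * n, class_domain=tuple(range(m)))
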