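import numpy as np
import pytest

from fastkendall.datasets import arcade_sample


@pytest.fixture(scope="session")
def arcade():
    """The 10-row doctorates-vs-arcade-revenue sample (no ties)."""
    return arcade_sample()


@pytest.fixture
def rng():
    return np.random.default_rng(20251002)


def brute_force_inversions(values) -> int:
    """O(n²) inversion count: pairs i<j with values[i] > values[j]."""
    vals = list(values)
    n = len(vals)
    return sum(
        1 for i in range(n) for j in range(i + 1, n) if vals[i] > vals[j]
    )
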