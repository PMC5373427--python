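import numpy as np
import pytest

from dendrocut import DataMatrix, MergeSequence, compute_linkage


@pytest.fixture
def three_points_1d() -> DataMatrix:
    """1-D points 0, 1, 10: merges at heights 1.0 and 9.5."""
    return DataMatrix(np.array([[0.0], [1.0], [10.0]]))


@pytest.fixture
def three_points_merges(three_points_1d) -> MergeSequence:
    return compute_linkage(three_points_1d)


def merges_from_heights(heights) -> MergeSequence:
    """A chain-shaped merge tree with the given heights (for estimator
    tests that only look at the height sequence)."""
    heights = np.asarray(heights, dtype=float)
    n = len(heights) + 1
    rows = []
    prev = 0
    for i, h in enumerate(heights):
        left = prev if i > 0 else 0
        if i == 0:
            rows.append([0, 1, h, 2])
        else:
            rows.append([n + i - 1, i + 1, h, i + 2])
    return MergeSequence(n_points=n, linkage_matrix=np.array(rows))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)
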