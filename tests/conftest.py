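import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from scenemap import LabeledMatrix, linkage, pairwise_distance


@pytest.fixture
def points015() -> LabeledMatrix:
    """Three 1-D points at 0, 1 and 5 — the standard worked micro-example."""
    return LabeledMatrix(np.array([[0.0], [1.0], [5.0]]), ["p0", "p1", "p5"], ["x"])


@pytest.fixture
def tree015_single(points015):
    d = pairwise_distance(points015, "rows", "euclidean")
    return linkage(d, "single", n_leaves=3)


def random_matrix(rng, max_n: int = 8):
    n = int(rng.integers(2, max_n + 1))
    m = int(rng.integers(2, max_n + 1))
    return LabeledMatrix(
        rng.standard_normal((n, m)),
        [f"r{i}" for i in range(n)],
        [f"c{j}" for j in range(m)],
    )
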