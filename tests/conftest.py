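import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from batfruitnet import InteractionMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_matrix(weights, animals=None, plants=None) -> InteractionMatrix:
    w = np.asarray(weights, dtype=float)
    a = animals or tuple(f"bat{i + 1}" for i in range(w.shape[0]))
    p = plants or tuple(f"plant{j + 1}" for j in range(w.shape[1]))
    return InteractionMatrix(tuple(a), tuple(p), w)


@pytest.fixture
def nested3() -> InteractionMatrix:
    """Perfectly nested 3x3: strictly decreasing marginals."""
    return make_matrix([[1, 1, 1], [1, 1, 0], [1, 0, 0]])


@pytest.fixture
def diagonal2() -> InteractionMatrix:
    return make_matrix([[1, 0], [0, 1]])


@pytest.fixture
def weighted_small() -> InteractionMatrix:
    return make_matrix([[4, 1], [1, 4]])


@pytest.fixture
def two_blocks() -> InteractionMatrix:
    """Two disconnected complete 2x2 blocks."""
    w = np.zeros((4, 4))
    w[:2, :2] = 1
    w[2:, 2:] = 1
    return make_matrix(w)
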