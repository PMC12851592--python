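import numpy as np
import pytest

from ommaquant.datatypes import Window


@pytest.fixture
def square_window():
    return Window(0.0, 100.0, 0.0, 100.0)


@pytest.fixture
def small_window():
    return Window(0.0, 20.0, 0.0, 20.0)


def brute_force_min_distance(points: np.ndarray) -> float:
    """All-pairs minimum distance by direct double loop (independent oracle)."""
    n = len(points)
    best = np.inf
    for i in range(n):
        for j in range(i + 1, n):
            d = np.hypot(*(points[i] - points[j]))
            best = min(best, d)
    return best
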