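import numpy as np
import pytest

from adapart import Mode, TimeCourse


@pytest.fixture
def two_level_tc() -> TimeCourse:
    """n=4, m=3: two clearly separated levels (1 and 11); total within-pair
    SSE of the optimal {1-2},{3-4} partition is 8."""
    return TimeCourse(
        [1, 2, 3, 4],
        [[0, 1, 2], [1, 2, 0], [10, 11, 12], [11, 12, 10]],
    )


@pytest.fixture
def random_tc():
    """Factory for random small instances in either mode."""

    def make(rng: np.random.Generator, n=None, mode=Mode.CONTINUOUS, max_m=5):
        if n is None:
            n = int(rng.integers(2, 9))
        obs = []
        for _ in range(n):
            m = int(rng.integers(1, max_m + 1))
            if Mode(mode) is Mode.BINARY:
                obs.append(rng.integers(0, 2, size=m).astype(float))
            else:
                obs.append(rng.normal(rng.integers(0, 3), 1.0, size=m))
        return TimeCourse(np.arange(1, n + 1, dtype=float), obs, mode)

    return make
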