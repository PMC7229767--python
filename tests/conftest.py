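import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from richsim import FrequencyCounts, IncidenceMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_matrix(values, is_error=None) -> IncidenceMatrix:
    """Build an IncidenceMatrix with generated labels from a nested list/array."""
    values = np.asarray(values)
    return IncidenceMatrix(
        values,
        [f"s{i}" for i in range(values.shape[0])],
        [f"u{j}" for j in range(values.shape[1])],
        is_error,
    )


def make_counts(T, s_obs, q1=0, q2=0, q3=0, q4=0, **rest) -> FrequencyCounts:
    """FrequencyCounts from Q1..Q4 plus a bulk class absorbing the remainder.

    The species not accounted for by Q1..Q4 are placed at the highest
    frequency class so the sum-to-S_obs invariant holds.
    """
    q = {1: q1, 2: q2, 3: q3, 4: q4}
    bulk = s_obs - sum(q.values())
    assert bulk >= 0, "Q1..Q4 exceed S_obs"
    if bulk:
        q[T] = q.get(T, 0) + bulk
    return FrequencyCounts(T=T, S_obs=s_obs, Q=q)


@pytest.fixture
def worked_matrix() -> IncidenceMatrix:
    """T=10, S_obs=20, Q1=4, Q2=2: the hand-checked Chao2/jackknife fixture."""
    values = np.zeros((20, 10), dtype=int)
    for i in range(4):  # singletons in units 0..3
        values[i, i] = 1
    values[4, :2] = 1  # doubletons
    values[5, 2:4] = 1
    values[6:, :] = 1  # 14 frequent species seen every day
    return make_matrix(values)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
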