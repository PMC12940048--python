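import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bold.preprocess import FeatureTable

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def planted_table():
    """Five attributes; attribute a1 is a noisy copy of the outcome."""
    rng = np.random.default_rng(0)
    n = 120
    y = (rng.random(n) < 0.5).astype(int)
    x1 = y + rng.normal(0, 0.3, n)
    noise = rng.random((n, 4))
    values = np.column_stack([x1, noise])
    return FeatureTable([f"a{i}" for i in range(1, 6)], values, y)


@pytest.fixture
def small_table():
    rng = np.random.default_rng(1)
    n = 60
    y = np.r_[np.zeros(30, dtype=int), np.ones(30, dtype=int)]
    values = rng.random((n, 3))
    values[:, 0] += 0.8 * y
    return FeatureTable(["u", "v", "w"], values, y)
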