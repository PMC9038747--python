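import numpy as np
import pytest

from soanfis.so import Bounds, SOConfig


@pytest.fixture
def unit_bounds5():
    return Bounds(np.zeros(5), np.ones(5))


@pytest.fixture
def sphere2_bounds():
    return Bounds(np.array([-5.0, -5.0]), np.array([5.0, 5.0]))


@pytest.fixture
def small_config():
    return SOConfig(population_size=10, fe_budget=200, rng_seed=0)


def neg_sphere(x):
    """Strength function maximized at the origin."""
    return -float(np.dot(x, x))


class CountingStrength:
    """Wraps a strength function and counts invocations."""

    def __init__(self, fn):
        self.fn = fn
        self.calls = 0

    def __call__(self, x):
        self.calls += 1
        return self.fn(x)


@pytest.fixture
def counting_sphere():
    return CountingStrength(neg_sphere)
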