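import numpy as np
import pytest

from admarker import synth


@pytest.fixture(scope="session")
def default_trial():
    """One default synthetic trial (three planted markers), shared read-only."""
    return synth.simulate_trial(synth.default_config(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_instance(rng, n_max=30):
    """A random (levels, flags) instance with both classes present and
    occasional ties."""
    n = int(rng.integers(4, n_max + 1))
    if rng.random() < 0.3:
        x = rng.integers(0, 5, n).astype(float)  # heavy ties
    else:
        x = rng.normal(size=n)
    while True:
        y = rng.random(n) < rng.uniform(0.2, 0.8)
        if y.any() and not y.all():
            return x, y
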