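import numpy as np
import pytest

from causaltrio.simulate import default_spec, simulate_triplet


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


def random_triplet(rng, n=60):
    """A generic random (g, x, y) data set with all three genotype levels."""
    g = rng.integers(0, 3, size=n)
    g[:3] = [0, 1, 2]  # guarantee every level occurs
    x = 0.4 * g + rng.normal(size=n)
    y = 0.3 * x + 0.2 * g + rng.normal(size=n)
    return g, x, y


@pytest.fixture
def triplet_b(rng):
    """One defaults replicate of the mediation scenario (b)."""
    return simulate_triplet(default_spec("b"), rng)
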