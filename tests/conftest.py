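import numpy as np
import pytest
from hypothesis import settings

from regiodist import PhantomSpec, make_atlas_phantom

settings.register_profile("default", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_masses(rng):
    """Factory for random unit-mass histogram vectors."""

    def make(bins=16):
        m = rng.random(bins) + 1e-6
        return m / m.sum()

    return make


@pytest.fixture(scope="session")
def tiny_spec():
    """A phantom small enough for per-test simulation."""
    return PhantomSpec(
        shape=(16, 16, 16),
        region_count=8,
        affected_regions=(1, 2),
        min_region_voxels=40,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_atlas(tiny_spec):
    return make_atlas_phantom(tiny_spec)
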