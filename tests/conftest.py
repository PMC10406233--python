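import numpy as np
import pytest

from restqc import phantom
from restqc.volio import BrainMask, Volume4D, VolumeGrid


@pytest.fixture
def small_grid():
    aff = np.diag([3.0, 3.0, 3.0, 1.0])
    return VolumeGrid(dims=(8, 8, 6), affine=aff)


@pytest.fixture
def cube_mask(small_grid):
    return BrainMask(grid=small_grid, member=np.ones(small_grid.dims, dtype=bool))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noise_volume(small_grid, rng):
    data = rng.normal(100.0, 5.0, size=small_grid.dims + (40,))
    return Volume4D(grid=small_grid, values=data)


@pytest.fixture(scope="session")
def quiet_subject():
    """A low-motion default subject, shared across tests (read-only)."""
    return phantom.simulate_subject(phantom.PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def mechanism_cohort():
    """The 40-subject cohort used for cohort-level checks (read-only)."""
    bundles, truth = phantom.simulate_cohort(40, seed=11)
    return bundles, truth
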