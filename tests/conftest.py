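import numpy as np
import pytest

from swalink.headmodel import generate_lead_field
from swalink.simulate import CohortConfig


@pytest.fixture(scope="session")
def lead_field():
    """Default 59-electrode, 6x6x6-voxel spherical lead field."""
    return generate_lead_field()


@pytest.fixture(scope="session")
def small_lead_field():
    """Cheap 24-electrode, 4x4x4-voxel lead field for inverse tests."""
    return generate_lead_field(n_electrodes=24, n_voxels_per_axis=4)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture()
def default_config():
    return CohortConfig(seed=11)
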