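import numpy as np
import pytest

from neurofluid.core import FrameSchedule
from neurofluid.synth.atlas import PhantomSpec, RegionDef, make_phantom_atlas


@pytest.fixture(scope="session")
def pib_schedule():
    return FrameSchedule.pib_default()


@pytest.fixture(scope="session")
def two_region_atlas():
    """Small phantom with a reference box (label 1) and a target box (label 2)."""
    spec = PhantomSpec(
        grid_shape=(8, 8, 4),
        voxel_size_mm=(2.0, 2.0, 2.0),
        region_defs=[
            RegionDef(1, "reference", "box", (2, 2, 1), (1, 1, 1)),
            RegionDef(2, "target", "box", (5, 5, 2), (1, 1, 1)),
        ],
    )
    return make_phantom_atlas(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
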