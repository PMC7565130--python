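import numpy as np
import pytest

from cscpet.segmentation import LesionVOI
from cscpet.synthetic import CompartmentSpec, PhantomSpec
from cscpet.volume import SUVVolume


def make_voi(suv_values, voxel_volume=0.064, **kwargs):
    """VOI helper: values laid out along one grid row."""
    suv = np.asarray(suv_values, dtype=float)
    indices = np.array([[0, 0, i] for i in range(suv.size)])
    return LesionVOI(indices=indices, suv=suv, voxel_volume=voxel_volume, **kwargs)


@pytest.fixture
def separated_phantom_spec():
    """Well-separated three-compartment phantom (means 3 / 5.5 / 9, SD 0.2)."""
    return PhantomSpec(
        shape=(24, 24, 24),
        compartments=(
            CompartmentSpec(3.0, 0.2, 60),
            CompartmentSpec(5.5, 0.2, 40),
            CompartmentSpec(9.0, 0.2, 14),
        ),
        seed=11,
    )


@pytest.fixture
def block_volume():
    """3x3x3 block of SUV 5 centered in a zero background, 4 mm grid."""
    data = np.zeros((9, 9, 9))
    data[3:6, 3:6, 3:6] = 5.0
    return SUVVolume(data=data, spacing=(4.0, 4.0, 4.0))
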