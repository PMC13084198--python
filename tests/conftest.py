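import numpy as np
import pytest

from thalafc.io_cohort import AcquisitionMeta, VoxelTimeSeriesImage
from thalafc.synthetic import PhantomSpec, build_phantom_geometry


def make_image(data, tr=2.0, voxel_size=(3.0, 3.0, 3.0), brain_mask=None):
    """Wrap a raw 4D array as a VoxelTimeSeriesImage with a full mask."""
    data = np.asarray(data, dtype=np.float64)
    if brain_mask is None:
        brain_mask = np.ones(data.shape[:3], dtype=bool)
    meta = AcquisitionMeta(
        repetition_time=tr, voxel_size=voxel_size, n_volumes=data.shape[3]
    )
    return VoxelTimeSeriesImage(data=data, meta=meta, brain_mask=brain_mask)


@pytest.fixture(scope="session")
def spec16():
    return PhantomSpec(grid_shape=(16, 16, 16), n_volumes=60)


@pytest.fixture(scope="session")
def geometry16(spec16):
    return build_phantom_geometry(spec16, seed=0)
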