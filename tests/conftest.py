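import numpy as np
import pytest

from boldopt.field_io import FieldMap, GradientField
from boldopt.protocol import get_preset


@pytest.fixture
def standard_protocol():
    return get_preset("standard")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_gradfield(rng):
    """Small random gradient field (uT/m) for optimizer tests."""
    shape = (10, 10, 10)
    gx, gy, gz = rng.uniform(-80, 80, size=(3, *shape))
    return GradientField(gx=gx, gy=gy, gz=gz, voxel_size=(3.0, 3.0, 3.0))


def constant_fieldmap(value=0.0, shape=(8, 8, 8), voxel_size=(3.0, 3.0, 3.0)):
    return FieldMap(values=np.full(shape, float(value)),
                    voxel_size=voxel_size)
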