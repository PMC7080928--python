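import numpy as np
import pytest

from focidose.stack_io import ChannelStack, VoxelGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def small_geometry():
    return VoxelGeometry(nx=16, ny=12, nz=4)


@pytest.fixture
def random_stack(rng, small_geometry):
    """A small two-channel stack with random uint16 intensities."""
    shape = small_geometry.shape
    return ChannelStack(
        channels={
            "DAPI": rng.integers(0, 4000, size=shape).astype(np.uint16),
            "H2AX": rng.integers(0, 4000, size=shape).astype(np.uint16),
        },
        geometry=small_geometry,
        metadata={"animal_id": "m01", "group": "4h", "tissue": "liver"},
    )
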