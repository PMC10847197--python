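import numpy as np
import pytest

from arrayfret.core_io import VoxelGeometry
from arrayfret.segmentation import _make_object
from arrayfret.synthetic import NoiseConfig, SimConfig


@pytest.fixture
def geom() -> VoxelGeometry:
    return VoxelGeometry(pixel_size_xy=100.0, section_thickness=70.0)


@pytest.fixture
def quiet_cfg(geom) -> SimConfig:
    """Small noise-free simulation: every render is exact."""
    return SimConfig(
        seed=11,
        n_sections=8,
        frame_size=(128, 128),
        geometry=geom,
        n_synapses=30,
        noise=NoiseConfig.off(),
    )


@pytest.fixture
def noisy_cfg(quiet_cfg) -> SimConfig:
    return quiet_cfg.replace(noise=NoiseConfig())


def make_object(voxels, geom, role="synaptic_post", obj_id=0):
    """Build an Object3D straight from a list of (section, row, col)."""
    return _make_object(obj_id, np.asarray(voxels, dtype=np.int64), geom, role)


@pytest.fixture
def object_factory(geom):
    def factory(voxels, role="synaptic_post", obj_id=0):
        return make_object(voxels, geom, role, obj_id)

    return factory
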