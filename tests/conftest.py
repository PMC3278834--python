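import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cellcycle3d.stack_io import LabeledObject

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_object(mask, intensity=None, voxel_size=(1.0, 1.0, 1.0), object_id=1,
                offset=(0, 0, 0)):
    """Build a LabeledObject from arrays (constant intensity 100 by default)."""
    mask = np.asarray(mask, dtype=bool)
    if intensity is None:
        intensity = np.full(mask.shape, 100.0)
    return LabeledObject(object_id=object_id, mask=mask,
                         intensity=np.asarray(intensity), offset=offset,
                         voxel_size=voxel_size)


def digitized_ball(radius_vox: float, pad: int = 3) -> np.ndarray:
    """Digitized ball of the given radius (in voxels) on an isotropic grid."""
    L = int(2 * radius_vox) + 2 * pad
    ax = np.arange(L) - (L - 1) / 2
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
    return zz**2 + yy**2 + xx**2 <= radius_vox**2


def digitized_ellipsoid(semi_axes, pad: int = 3) -> np.ndarray:
    """Solid axis-aligned ellipsoid with semi-axes (az, ay, ax) in voxels."""
    az, ay, axx = semi_axes
    shape = tuple(int(2 * s) + 2 * pad for s in (az, ay, axx))
    grids = [np.arange(n) - (n - 1) / 2 for n in shape]
    zz, yy, xx = np.meshgrid(*grids, indexing="ij", sparse=True)
    return (zz / az) ** 2 + (yy / ay) ** 2 + (xx / axx) ** 2 <= 1.0


def random_small_object(rng, max_side=6, levels=8, voxel_size=(1.0, 1.0, 1.0)):
    """A random connected-ish blob with random quantizable intensities."""
    shape = tuple(rng.integers(2, max_side + 1, size=3))
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    intensity = rng.integers(0, 256, size=shape).astype(float)
    return make_object(mask, intensity, voxel_size=voxel_size), levels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
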