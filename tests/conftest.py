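import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def voxel_face_area_nm2(mask: np.ndarray, spacing_zyx) -> float:
    """Naive exposed-voxel-face surface area (nm^2), kept as a test oracle.

    Systematically overestimates the area of smooth objects (~1.5x on
    spheres) and therefore upper-bounds the mesh estimate on convex
    phantoms.
    """
    dz, dy, dx = spacing_zyx
    m = np.pad(np.asarray(mask, bool), 1)
    area = 0.0
    face = {0: dy * dx, 1: dz * dx, 2: dz * dy}
    for axis in range(3):
        fwd = np.diff(m.astype(np.int8), axis=axis)
        area += np.count_nonzero(fwd) * face[axis]
    return area


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
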