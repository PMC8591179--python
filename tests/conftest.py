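"""Shared fixtures: digitized-sphere tumor phantoms and scaled study configs.

The sphere is the geometry oracle workhorse — every distance, volume and
area it produces has a closed form.  It is digitized with its center on a
voxel center so that trilinear interpolation of the distance field is
exact there (the field has a cone apex at the center which off-grid
interpolation would clip).
"""

import numpy as np
import pytest

from osteomargin.phantom import Volume3D
from osteomargin import segmentation


SPHERE_RADIUS = 10.0
SPHERE_SPACING = 0.5


def make_sphere_label(
    radius: float = SPHERE_RADIUS,
    spacing: float = SPHERE_SPACING,
    half_extent: float = 24.0,
) -> Volume3D:
    """Binary sphere label on a grid whose center voxel is at the origin."""
    g = np.arange(-half_extent, half_extent + spacing / 2, spacing)
    assert 0.0 in g
    r2 = (g**2)[:, None, None] + (g**2)[None, :, None] + (g**2)[None, None, :]
    return Volume3D((r2 <= radius**2).astype(np.int16), (spacing,) * 3, (g[0],) * 3)


@pytest.fixture(scope="session")
def sphere_label() -> Volume3D:
    return make_sphere_label()


@pytest.fixture(scope="session")
def sphere_sdf(sphere_label):
    return segmentation.signed_distance(sphere_label)


@pytest.fixture(scope="session")
def sphere_mesh(sphere_label):
    return segmentation.extract_surface(sphere_label)


@pytest.fixture(scope="session")
def scaled_config():
    """A study config small enough for fast end-to-end tests."""
    from osteomargin.pipeline import StudyConfig

    return StudyConfig(seed=11, volume_shape=(96, 96, 96), voxel_spacing_mm=1.5)


@pytest.fixture(scope="session")
def voxel_diagonal() -> float:
    return float(np.sqrt(3) * SPHERE_SPACING)
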