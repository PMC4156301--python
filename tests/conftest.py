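"""Shared fixtures: small grids, geometries and test images."""

import numpy as np
import pytest
import scipy.ndimage as ndi

from mdart import (
    GreyLevelModel,
    Image,
    ImageGrid,
    JosephOperator,
    Sinogram,
    default_geometry,
    disk_with_holes,
    forward_project,
)


@pytest.fixture
def grid16():
    return ImageGrid(16, 16, 1.0)


@pytest.fixture
def grid8():
    return ImageGrid(8, 8, 1.0)


@pytest.fixture
def binary_model():
    return GreyLevelModel((0.0, 1.0))


@pytest.fixture
def smooth_blob16(grid16):
    """Smooth random field with compact support and a background margin.

    Feature scale is several pixels and the mass near the grid border is
    negligible, so different line-integral discretizations agree closely.
    """
    xx, yy = grid16.pixel_centers()
    r2 = xx**2 + yy**2
    rng = np.random.default_rng(1)
    field = np.exp(-r2 / (2 * 3.0**2)) * (
        1.0 + 0.2 * ndi.gaussian_filter(rng.standard_normal(grid16.shape), 2.5)
    )
    return Image(grid16, field)


@pytest.fixture
def disk_system_8(grid8):
    """Tiny consistent system: 8x8 disk, 16 parallel angles, fine detector."""
    from mdart import make_equiangular_geometry

    xx, yy = grid8.pixel_centers()
    disk = Image(grid8, ((xx**2 + yy**2) <= 3.0**2).astype(float))
    geometry = make_equiangular_geometry(
        "parallel", 16, 180.0, 0.0, n_detectors=24, detector_pixel_size=0.5
    )
    operator = JosephOperator(geometry, grid8)
    sinogram = Sinogram(geometry, operator.apply(disk.values))
    return disk, operator, sinogram


@pytest.fixture
def dart_problem_64():
    """64x64 disk with 3 holes and its 15-view fan-beam sinogram."""
    grid = ImageGrid(64, 64, 1.0)
    phantom = disk_with_holes(64, disk_radius=24, hole_radius=5, n_holes=3, seed=0)
    geometry = default_geometry(grid, 15, "fan")
    sinogram = forward_project(phantom, geometry)
    return phantom, grid, sinogram
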