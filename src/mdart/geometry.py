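"""Core geometric containers for 2-D tomography.

Conventions
-----------
World coordinates are centered on the rotation axis: x to the right, y up,
angles in radians measured counter-clockwise from the x-axis.  The
reconstruction grid is a square raster of ``n`` x ``n`` pixels of physical
side ``pixel_size``, centered on the origin, with row 0 at the top (so row
index increases as world y decreases).  The detector is a 1-D array of bins
centered on the beam axis.

Projection angles are sampled on the half-open interval
``[0, angular_range - missing_wedge)`` so that e.g. ``n`` equiangular
parallel-beam views over 180 degrees never duplicate the 0/180 pair.  A
missing wedge is carved out of the top of the angular range: the covered
range shrinks, the angular step adapts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class GeometryError(ValueError):
    """Raised for inconsistent or unsupported acquisition geometries."""


@dataclass(frozen=True)
class ImageGrid:
    """A square pixel raster with a physical pixel size.

    The physical field of view is ``n_cols * pixel_size`` in both directions;
    it is preserved (not cropped) when the grid is coarsened or refined, so
    grids at different resolutions describe the same physical region.
    """

    n_rows: int
    n_cols: int
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.n_rows != self.n_cols:
            raise GeometryError(
                f"only square grids are supported, got {self.n_rows}x{self.n_cols}"
            )
        if self.n_rows < 1:
            raise GeometryError("grid must contain at least one pixel")
        if not (self.pixel_size > 0):
            raise GeometryError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def extent(self) -> float:
        """Physical side length of the field of view."""
        return self.n_cols * self.pixel_size

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """World (x, y) coordinates of pixel centers as 2-D arrays.

        Element ``[r, c]`` holds the center of the pixel in row ``r``,
        column ``c``.
        """
        half = (self.n_cols - 1) / 2.0
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = (cols[None, :] - half) * self.pixel_size
        y = (half - rows[:, None]) * self.pixel_size
        return np.broadcast_to(x, self.shape).copy(), np.broadcast_to(y, self.shape).copy()


@dataclass
class Image:
    """A real-valued attenuation map on an :class:`ImageGrid`."""

    grid: ImageGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")

    def copy(self) -> "Image":
        return Image(self.grid, self.values.copy())

    @classmethod
    def zeros(cls, grid: ImageGrid) -> "Image":
        return cls(grid, np.zeros(grid.shape))

    @classmethod
    def full(cls, grid: ImageGrid, value: float) -> "Image":
        return cls(grid, np.full(grid.shape, float(value)))


@dataclass(frozen=True)
class ProjectionGeometry:
    """Equiangular fan- or parallel-beam acquisition geometry.

    Parameters
    ----------
    beam:
        ``"parallel"`` or ``"fan"``.
    angles:
        Strictly increasing projection angles in radians.
    n_detectors, detector_pixel_size:
        Detector bin count and physical bin width.
    source_object_distance, source_detector_distance:
        Fan beam only: distance from the point source to the rotation axis
        and to the (flat) detector line, both along the central beam axis.
    angular_range_deg, missing_wedge_deg:
        Nominal full angular range of the scan and the contiguous wedge of
        angles that was not acquired; the covered range is their difference.
    """

    beam: str
    angles: np.ndarray
    n_detectors: int
    detector_pixel_size: float = 1.0
    source_object_distance: float | None = None
    source_detector_distance: float | None = None
    angular_range_deg: float = 360.0
    missing_wedge_deg: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "angles", np.atleast_1d(np.asarray(self.angles, dtype=float)))
        if self.beam not in ("parallel", "fan"):
            raise GeometryError(f"unknown beam type {self.beam!r}")
        if self.angles.size < 1:
            raise GeometryError("at least one projection angle is required")
        if self.angles.size > 1 and not np.all(np.diff(self.angles) > 0):
            raise GeometryError("angles must be strictly increasing")
        if self.n_detectors < 1:
            raise GeometryError("n_detectors must be >= 1")
        if not (self.detector_pixel_size > 0):
            raise GeometryError("detector_pixel_size must be positive")
        if self.missing_wedge_deg < 0:
            raise GeometryError("missing_wedge_deg must be >= 0")
        if self.missing_wedge_deg >= self.angular_range_deg:
            raise GeometryError("missing wedge must be smaller than the angular range")
        if self.beam == "fan":
            d_so = self.source_object_distance
            d_sd = self.source_detector_distance
            if d_so is None or d_sd is None:
                raise GeometryError("fan beam requires source-object and source-detector distances")
            if not (d_sd > d_so > 0):
                raise GeometryError(
                    "fan beam requires source_detector_distance > source_object_distance > 0"
                )

    @property
    def n_angles(self) -> int:
        return int(self.angles.size)

    @property
    def n_rays(self) -> int:
        return self.n_angles * self.n_detectors

    @property
    def magnification(self) -> float:
        """Geometric magnification at the rotation axis (1 for parallel beam)."""
        if self.beam == "parallel":
            return 1.0
        return self.source_detector_distance / self.source_object_distance

    def detector_centers(self) -> np.ndarray:
        """Signed offsets of detector bin centers along the detector axis."""
        half = (self.n_detectors - 1) / 2.0
        return (np.arange(self.n_detectors) - half) * self.detector_pixel_size

    def to_dict(self) -> dict:
        d = {
            "beam": self.beam,
            "angles": self.angles.tolist(),
            "n_detectors": int(self.n_detectors),
            "detector_pixel_size": float(self.detector_pixel_size),
            "angular_range_deg": float(self.angular_range_deg),
            "missing_wedge_deg": float(self.missing_wedge_deg),
        }
        if self.beam == "fan":
            d["source_object_distance"] = float(self.source_object_distance)
            d["source_detector_distance"] = float(self.source_detector_distance)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectionGeometry":
        if "beam" not in d:
            raise GeometryError("geometry dictionary is missing the beam type")
        return cls(
            beam=d["beam"],
            angles=np.asarray(d["angles"], dtype=float),
            n_detectors=int(d["n_detectors"]),
            detector_pixel_size=float(d.get("detector_pixel_size", 1.0)),
            source_object_distance=d.get("source_object_distance"),
            source_detector_distance=d.get("source_detector_distance"),
            angular_range_deg=float(d.get("angular_range_deg", 360.0)),
            missing_wedge_deg=float(d.get("missing_wedge_deg", 0.0)),
        )


@dataclass
class Sinogram:
    """Measured line integrals: an (n_angles x n_detectors) matrix on a geometry."""

    geometry: ProjectionGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = (self.geometry.n_angles, self.geometry.n_detectors)
        if self.values.shape != expected:
            raise ValueError(
                f"sinogram shape {self.values.shape} does not match geometry {expected}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sinogram values must be finite")

    def copy(self) -> "Sinogram":
        return Sinogram(self.geometry, self.values.copy())

    def norm(self) -> float:
        """Euclidean norm of the data vector."""
        return float(np.linalg.norm(self.values))


def make_equiangular_geometry(
    beam: str,
    n_angles: int,
    angular_range_deg: float,
    missing_wedge_deg: float = 0.0,
    *,
    n_detectors: int,
    detector_pixel_size: float = 1.0,
    source_object_distance: float | None = None,
    source_detector_distance: float | None = None,
) -> ProjectionGeometry:
    """Build an equiangular geometry over a possibly wedge-limited range.

    ``n_angles`` angles are placed uniformly on the half-open interval
    ``[0, angular_range - missing_wedge)`` degrees (converted to radians).
    The wedge is removed from the top of the range; since the phantom
    orientation is arbitrary, any contiguous wedge placement is equivalent
    up to a rotation of the object.
    """
    if n_angles < 1:
        raise GeometryError("n_angles must be >= 1")
    if not (0 <= missing_wedge_deg < angular_range_deg):
        raise GeometryError(
            f"missing wedge ({missing_wedge_deg} deg) must lie in [0, {angular_range_deg})"
        )
    covered = angular_range_deg - missing_wedge_deg
    step = covered / n_angles
    angles = np.deg2rad(np.arange(n_angles) * step)
    return ProjectionGeometry(
        beam=beam,
        angles=angles,
        n_detectors=n_detectors,
        detector_pixel_size=detector_pixel_size,
        source_object_distance=source_object_distance,
        source_detector_distance=source_detector_distance,
        angular_range_deg=angular_range_deg,
        missing_wedge_deg=missing_wedge_deg,
    )


def coarsen_grid(grid: ImageGrid, k: int) -> ImageGrid:
    """Coarsen a grid by a factor ``2**k`` while preserving the field of view.

    The side shrinks by ``2**k`` and the pixel size grows by the same factor,
    so the physical extent is unchanged.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    factor = 2**k
    if grid.n_cols % factor != 0:
        raise GeometryError(
            f"grid side {grid.n_cols} is not divisible by 2^{k} = {factor}"
        )
    return ImageGrid(
        n_rows=grid.n_rows // factor,
        n_cols=grid.n_cols // factor,
        pixel_size=grid.pixel_size * factor,
    )
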