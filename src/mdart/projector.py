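"""Joseph's ray-driven forward and back projector.

For every ray the projector marches along the ray's dominant axis one pixel
row (or column) at a time and linearly interpolates the image between the
two pixel centers adjacent to the ray on the minor axis.  Each step
contributes interpolated value times the ray path length per step,
``pixel_size / |d_major|`` for a unit direction vector ``d``, so projection
values carry physical length units and scale linearly with the pixel size.

The interpolation weights depend only on the (geometry, grid) pair, so the
operator assembles them once into a sparse matrix and reuses it for forward
projection, back projection (the exact transpose, which makes the adjoint
identity hold to machine precision) and the row/column sums needed by SIRT.
A dense materialization is available for tiny grids only, as a testing aid.

A deliberately naive dense-sampling line integral (:func:`oracle_line_integral`)
is provided as an independent cross-check for tests; it shares no code with
the Joseph kernel.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .geometry import Image, ImageGrid, ProjectionGeometry, Sinogram

#: largest grid side for which a dense system matrix may be materialized
DENSE_LIMIT = 16


def ray_parameters(geometry: ProjectionGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Anchor points and unit directions for every ray.

    Returns
    -------
    points, directions:
        Arrays of shape ``(n_angles, n_detectors, 2)``.  For a parallel beam
        the anchor is the detector bin center projected onto the line through
        the origin; for a fan beam the anchor is the source position and the
        direction points from the source through the detector bin center.
    """
    t = geometry.detector_centers()  # (n_det,)
    n_a, n_d = geometry.n_angles, geometry.n_detectors
    points = np.empty((n_a, n_d, 2))
    dirs = np.empty((n_a, n_d, 2))
    for i, theta in enumerate(geometry.angles):
        u = np.array([np.cos(theta), np.sin(theta)])  # detector axis
        v = np.array([-np.sin(theta), np.cos(theta)])  # central beam direction
        if geometry.beam == "parallel":
            points[i] = t[:, None] * u[None, :]
            dirs[i] = v[None, :]
        else:
            source = -geometry.source_object_distance * v
            det = source + geometry.source_detector_distance * v + t[:, None] * u[None, :]
            d = det - source
            d /= np.linalg.norm(d, axis=1, keepdims=True)
            points[i] = source
            dirs[i] = d
    return points, dirs


def _joseph_entries(
    points: np.ndarray, dirs: np.ndarray, grid: ImageGrid
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sparse (ray, pixel, weight) triplets for one batch of rays.

    ``points``/``dirs`` have shape (n_rays, 2).  Rays are split by dominant
    axis; x-dominant rays march over columns, y-dominant rays over rows.
    Interpolation neighbors that fall outside the grid are dropped, so rays
    missing the grid simply produce no entries.
    """
    n = grid.n_cols
    h = grid.pixel_size
    half = (n - 1) / 2.0
    rows_out, cols_out, w_out = [], [], []

    x_dom = np.abs(dirs[:, 0]) >= np.abs(dirs[:, 1])
    for axis, sel in ((0, x_dom), (1, ~x_dom)):
        if not np.any(sel):
            continue
        P, V = points[sel], dirs[sel]
        ray_ids = np.nonzero(sel)[0]
        major = np.arange(n)
        if axis == 0:
            # world x of each column; interpolate along rows
            xs = (major - half) * h
            slope = V[:, 1] / V[:, 0]
            y = P[:, 1, None] + (xs[None, :] - P[:, 0, None]) * slope[:, None]
            minor = half - y / h  # fractional row index
            step_len = h / np.abs(V[:, 0])
        else:
            ys = (half - major) * h
            slope = V[:, 0] / V[:, 1]
            x = P[:, 0, None] + (ys[None, :] - P[:, 1, None]) * slope[:, None]
            minor = x / h + half  # fractional column index
            step_len = h / np.abs(V[:, 1])

        i0 = np.floor(minor).astype(np.int64)
        frac = minor - i0
        ray_mat = np.broadcast_to(ray_ids[:, None], minor.shape)
        major_mat = np.broadcast_to(major[None, :], minor.shape)
        len_mat = np.broadcast_to(step_len[:, None], minor.shape)
        for idx, wgt in ((i0, 1.0 - frac), (i0 + 1, frac)):
            valid = (idx >= 0) & (idx < n) & (wgt > 0)
            if axis == 0:
                pix = idx[valid] * n + major_mat[valid]
            else:
                pix = major_mat[valid] * n + idx[valid]
            rows_out.append(ray_mat[valid])
            cols_out.append(pix)
            w_out.append(wgt[valid] * len_mat[valid])

    if not rows_out:
        empty = np.empty(0)
        return empty.astype(np.int64), empty.astype(np.int64), empty
    return (
        np.concatenate(rows_out),
        np.concatenate(cols_out),
        np.concatenate(w_out),
    )


class JosephOperator:
    """Matrix-backed Joseph projector for a fixed (geometry, grid) pair.

    Forward application maps an image to a sinogram; the adjoint is the
    transpose of the same weight matrix, so ``<Wx, y> == <x, W^T y>`` holds
    to floating-point round-off by construction.
    """

    def __init__(self, geometry: ProjectionGeometry, grid: ImageGrid):
        self.geometry = geometry
        self.grid = grid
        points, dirs = ray_parameters(geometry)
        rows, cols, weights = _joseph_entries(
            points.reshape(-1, 2), dirs.reshape(-1, 2), grid
        )
        self.matrix = sp.csr_matrix(
            (weights, (rows, cols)), shape=(geometry.n_rays, grid.n_pixels)
        )
        self._matrix_T = self.matrix.T.tocsr()

    # -- linear maps ---------------------------------------------------
    def apply(self, values: np.ndarray) -> np.ndarray:
        """Forward projection of a flat or 2-D pixel array to (n_angles, n_det)."""
        flat = np.asarray(values, dtype=float).reshape(-1)
        if flat.size != self.grid.n_pixels:
            raise ValueError("image size does not match the operator grid")
        out = self.matrix @ flat
        return out.reshape(self.geometry.n_angles, self.geometry.n_detectors)

    def adjoint(self, sino_values: np.ndarray) -> np.ndarray:
        """Back projection of a sinogram array to the grid shape."""
        flat = np.asarray(sino_values, dtype=float).reshape(-1)
        if flat.size != self.geometry.n_rays:
            raise ValueError("sinogram size does not match the operator geometry")
        out = self._matrix_T @ flat
        return out.reshape(self.grid.shape)

    # -- SIRT normalizations -------------------------------------------
    def row_sums(self) -> np.ndarray:
        """Per-ray sums of projection weights, shape (n_angles, n_det).

        Equals the forward projection of an all-ones image.  Zero for rays
        that miss the grid entirely.
        """
        return np.asarray(self.matrix.sum(axis=1)).reshape(
            self.geometry.n_angles, self.geometry.n_detectors
        )

    def col_sums(self) -> np.ndarray:
        """Per-pixel sums of projection weights (back projection of ones)."""
        return np.asarray(self.matrix.sum(axis=0)).reshape(self.grid.shape)

    def dense(self) -> np.ndarray:
        """Explicit dense system matrix; restricted to tiny testing grids."""
        if self.grid.n_cols > DENSE_LIMIT:
            raise ValueError(
                f"dense construction is limited to grids of side <= {DENSE_LIMIT}"
            )
        return self.matrix.toarray()


def _check_detector_coverage(geometry: ProjectionGeometry, grid: ImageGrid) -> None:
    # the detector must at least span the grid's inscribed circle (scaled by
    # the fan magnification at the rotation axis)
    span = geometry.n_detectors * geometry.detector_pixel_size
    needed = grid.extent * geometry.magnification
    if span + 1e-9 < needed:
        raise ValueError(
            f"detector span {span:g} is too short to cover the field of view "
            f"({needed:g} after magnification)"
        )


def forward_project(image: Image, geometry: ProjectionGeometry) -> Sinogram:
    """Joseph forward projection of an image.

    The detector must span the grid's inscribed circle (after fan
    magnification); shorter detectors would silently truncate the object.
    """
    _check_detector_coverage(geometry, image.grid)
    op = JosephOperator(geometry, image.grid)
    return Sinogram(geometry, op.apply(image.values))


def back_project(sinogram: Sinogram, grid: ImageGrid) -> Image:
    """Exact adjoint of :func:`forward_project` on the given grid."""
    _check_detector_coverage(sinogram.geometry, grid)
    op = JosephOperator(sinogram.geometry, grid)
    return Image(grid, op.adjoint(sinogram.values))


def oracle_line_integral(
    image: Image, point: np.ndarray, direction: np.ndarray, step: float
) -> float:
    """Brute-force line integral by dense sampling with nearest-pixel lookup.

    Riemann sum of the piecewise-constant image along the ray through
    ``point`` with unit ``direction``, sampled every ``step`` length units.
    Converges to the true integral of the pixelated image as ``step -> 0``.
    Intended as an independent test oracle; never used by the projector.
    """
    if not (step > 0):
        raise ValueError("step must be positive")
    point = np.asarray(point, dtype=float)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    grid = image.grid
    n, h = grid.n_cols, grid.pixel_size
    half = (n - 1) / 2.0
    # sample a segment guaranteed to contain the grid: the grid lies within
    # a circle of radius extent around the origin
    radius = grid.extent  # generous bound (> diagonal/2)
    t0 = float(np.dot(-point, direction))  # closest approach to origin
    ts = np.arange(t0 - radius, t0 + radius + step, step)
    pts = point[None, :] + ts[:, None] * direction[None, :]
    cols = np.rint(pts[:, 0] / h + half).astype(int)
    rows = np.rint(half - pts[:, 1] / h).astype(int)
    inside = (rows >= 0) & (rows < n) & (cols >= 0) & (cols < n)
    if not np.any(inside):
        return 0.0
    return float(np.sum(image.values[rows[inside], cols[inside]]) * step)
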