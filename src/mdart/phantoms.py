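"""Parametric phantom generators for discrete-tomography experiments.

All generators rasterize analytic shapes with a pixel-center membership
rule: a pixel belongs to a shape iff its center lies inside.  This keeps
the images exactly discrete (only the declared grey values occur), which is
the prior discrete reconstruction relies on; anti-aliasing is deliberately
avoided.  Stochastic generators are reproducible from their seed.

Phantoms are typically rasterized at a finer grid than the reconstruction
(an oversampling factor, default 2) so that pixelation of the ground truth
does not dominate the evaluation; :func:`oversampled_grid` builds the
matching fine grid for a given reconstruction grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Image, ImageGrid


class PackingError(RuntimeError):
    """Raised when random hole placement cannot satisfy the constraints."""


_MAX_ATTEMPTS = 10_000


def oversampled_grid(grid: ImageGrid, factor: int = 2) -> ImageGrid:
    """A grid with ``factor`` times the side and the same physical extent."""
    if factor < 1:
        raise ValueError("oversampling factor must be >= 1")
    return ImageGrid(grid.n_rows * factor, grid.n_cols * factor, grid.pixel_size / factor)


def _centered_coords(size: int) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates in pixel units, origin at the image center."""
    half = (size - 1) / 2.0
    c = np.arange(size) - half
    x = np.broadcast_to(c[None, :], (size, size))
    y = np.broadcast_to(-c[:, None], (size, size))
    return x, y


def disk_with_holes(
    size: int,
    disk_radius: float | None = None,
    hole_radius: float = 5.0,
    n_holes: int = 3,
    seed: int = 0,
    pixel_size: float = 1.0,
) -> Image:
    """Binary disk with randomly placed, non-overlapping circular holes.

    Hole centers are rejection-sampled uniformly inside the disk such that
    holes neither overlap each other nor cross the disk edge.  ``disk_radius``
    defaults to 40% of the image side.  Radii are in pixels.
    """
    if disk_radius is None:
        disk_radius = 0.4 * size
    if disk_radius <= 0 or hole_radius <= 0:
        raise ValueError("radii must be positive")
    if n_holes < 0:
        raise ValueError("n_holes must be >= 0")
    if n_holes > 0 and hole_radius >= disk_radius:
        raise PackingError("holes cannot fit inside the disk")

    rng = np.random.default_rng(seed)
    centers: list[tuple[float, float]] = []
    max_c = disk_radius - hole_radius  # hole must stay inside the disk
    attempts = 0
    while len(centers) < n_holes:
        if attempts >= _MAX_ATTEMPTS:
            raise PackingError(
                f"failed to place {n_holes} holes of radius {hole_radius} "
                f"in a disk of radius {disk_radius} after {attempts} attempts"
            )
        attempts += 1
        cx, cy = rng.uniform(-max_c, max_c, size=2)
        if cx * cx + cy * cy > max_c * max_c:
            continue
        if any((cx - px) ** 2 + (cy - py) ** 2 < (2 * hole_radius) ** 2 for px, py in centers):
            continue
        centers.append((cx, cy))

    x, y = _centered_coords(size)
    values = (x * x + y * y <= disk_radius**2).astype(float)
    for cx, cy in centers:
        values[(x - cx) ** 2 + (y - cy) ** 2 <= hole_radius**2] = 0.0
    return Image(ImageGrid(size, size, pixel_size), values)


def siemens_star(
    size: int,
    n_spokes: int = 8,
    inner_radius: float | None = None,
    outer_radius: float | None = None,
    pixel_size: float = 1.0,
) -> Image:
    """Binary star of ``n_spokes`` alternating angular sectors.

    The annulus between the radii is divided into ``2 * n_spokes`` sectors
    of equal angular width, alternating foreground/background, which gives
    2-fold rotational symmetry for even ``n_spokes``.
    """
    if n_spokes < 1 or n_spokes % 2 != 0:
        raise ValueError("n_spokes must be a positive even number")
    if inner_radius is None:
        inner_radius = 0.04 * size
    if outer_radius is None:
        outer_radius = 0.4 * size
    if not (0 <= inner_radius < outer_radius):
        raise ValueError("radii must satisfy 0 <= inner < outer")
    x, y = _centered_coords(size)
    r = np.hypot(x, y)
    theta = np.mod(np.arctan2(y, x), 2 * np.pi)
    sector = np.floor(theta / (np.pi / n_spokes)).astype(int)
    values = ((sector % 2 == 0) & (r >= inner_radius) & (r <= outer_radius)).astype(float)
    return Image(ImageGrid(size, size, pixel_size), values)


@dataclass(frozen=True)
class EllipseSpec:
    """One ellipse: center (pixels from image center), semi-axes, rotation, value."""

    cx: float
    cy: float
    a: float
    b: float
    rotation_deg: float = 0.0
    value: float = 1.0


def ellipses_phantom(
    size: int, ellipses: list[EllipseSpec], pixel_size: float = 1.0
) -> Image:
    """Composite of (possibly intersecting) ellipses; later ones overwrite.

    Raises if an ellipse extends beyond the image, so the phantom always
    keeps a background margin.
    """
    x, y = _centered_coords(size)
    values = np.zeros((size, size))
    half = size / 2.0
    for e in ellipses:
        if e.a <= 0 or e.b <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        reach = max(e.a, e.b)
        if abs(e.cx) + reach > half or abs(e.cy) + reach > half:
            raise ValueError(f"ellipse {e} extends outside the grid")
        phi = np.deg2rad(e.rotation_deg)
        dx, dy = x - e.cx, y - e.cy
        u = dx * np.cos(phi) + dy * np.sin(phi)
        v = -dx * np.sin(phi) + dy * np.cos(phi)
        inside = (u / e.a) ** 2 + (v / e.b) ** 2 <= 1.0
        values[inside] = e.value
    return Image(ImageGrid(size, size, pixel_size), values)


def three_grey_ellipses(size: int, pixel_size: float = 1.0) -> Image:
    """A default composite of intersecting ellipses with three grey values."""
    s = size / 128.0  # shapes defined on a 128-px reference frame
    ellipses = [
        EllipseSpec(0.0, 0.0, 48 * s, 34 * s, 15.0, 0.5),
        EllipseSpec(-14 * s, 8 * s, 22 * s, 14 * s, -20.0, 1.0),
        EllipseSpec(16 * s, -10 * s, 16 * s, 24 * s, 30.0, 1.0),
        EllipseSpec(6 * s, 14 * s, 10 * s, 6 * s, 0.0, 0.5),
    ]
    return ellipses_phantom(size, ellipses, pixel_size)


@dataclass(frozen=True)
class Primitive:
    """Boolean raster primitive: rect | disk | annulus, added or subtracted."""

    shape: str  # "rect", "disk", "annulus"
    op: str = "add"  # "add" or "subtract"
    cx: float = 0.0
    cy: float = 0.0
    width: float = 0.0  # rect
    height: float = 0.0  # rect
    radius: float = 0.0  # disk / annulus outer
    inner_radius: float = 0.0  # annulus


def structured_binary(
    size: int,
    primitives: list[Primitive] | None = None,
    seed: int = 0,
    pixel_size: float = 1.0,
) -> Image:
    """Binary composition of rectangles, disks and annuli.

    A synthetic stand-in for machined-part-style objects: a binary image
    with straight edges, drilled holes and thin annular walls.  With
    ``primitives=None``, a default engine-component-like composition is
    generated with small seeded jitter on the hole positions.
    """
    if primitives is None:
        primitives = _default_structured_primitives(size, seed)
    if not primitives:
        raise ValueError("primitive list must not be empty")
    x, y = _centered_coords(size)
    values = np.zeros((size, size), dtype=bool)
    for p in primitives:
        if p.shape == "rect":
            inside = (np.abs(x - p.cx) <= p.width / 2) & (np.abs(y - p.cy) <= p.height / 2)
        elif p.shape == "disk":
            inside = (x - p.cx) ** 2 + (y - p.cy) ** 2 <= p.radius**2
        elif p.shape == "annulus":
            r2 = (x - p.cx) ** 2 + (y - p.cy) ** 2
            inside = (r2 <= p.radius**2) & (r2 >= p.inner_radius**2)
        else:
            raise ValueError(f"unknown primitive shape {p.shape!r}")
        if p.op == "add":
            values |= inside
        elif p.op == "subtract":
            values &= ~inside
        else:
            raise ValueError(f"unknown primitive op {p.op!r}")
    return Image(ImageGrid(size, size, pixel_size), values.astype(float))


def _default_structured_primitives(size: int, seed: int) -> list[Primitive]:
    """Machined-part-like default: block + bores + thin annular chambers."""
    rng = np.random.default_rng(seed)
    s = size / 128.0
    jit = lambda scale: float(rng.uniform(-scale, scale))  # noqa: E731
    prims = [
        Primitive("rect", "add", 0.0, 0.0, 88 * s, 72 * s),
        Primitive("disk", "add", -44 * s, 0.0, radius=36 * s),
        Primitive("disk", "add", 44 * s, 0.0, radius=36 * s),
        Primitive("annulus", "subtract", -24 * s + jit(2 * s), 12 * s + jit(2 * s),
                  radius=14 * s, inner_radius=9 * s),
        Primitive("annulus", "subtract", 24 * s + jit(2 * s), 12 * s + jit(2 * s),
                  radius=14 * s, inner_radius=9 * s),
        Primitive("disk", "subtract", -24 * s + jit(2 * s), -16 * s, radius=6 * s),
        Primitive("disk", "subtract", 24 * s + jit(2 * s), -16 * s, radius=6 * s),
        Primitive("rect", "subtract", 0.0, -28 * s + jit(s), 52 * s, 8 * s),
        Primitive("disk", "subtract", 0.0, 16 * s + jit(s), radius=5 * s),
    ]
    return prims


def phantom_batch(
    kind: str, size: int, n_phantoms: int, seed: int = 0, **kwargs
) -> list[Image]:
    """Independent phantom replicates for sweep experiments (>= 3 per setting)."""
    if n_phantoms < 1:
        raise ValueError("n_phantoms must be >= 1")
    out = []
    for i in range(n_phantoms):
        if kind == "disk_with_holes":
            out.append(disk_with_holes(size, seed=seed + i, **kwargs))
        elif kind == "structured_binary":
            out.append(structured_binary(size, seed=seed + i, **kwargs))
        else:
            raise ValueError(f"batch generation is defined for stochastic kinds, not {kind!r}")
    return out
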