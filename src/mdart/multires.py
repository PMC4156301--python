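"""Coarse-to-fine multiresolution DART (MDART).

Few-view and missing-wedge data make the algebraic system severely
underdetermined on the target grid, so the initial reconstruction — and
hence the first DART segmentations — can be dominated by artefacts.
Coarsening the grid keeps the number of equations while shrinking the
number of unknowns, which makes the coarse problem far better posed.  MDART
therefore runs DART to convergence on a coarse grid first, bilinearly
upsamples the continuous result, and uses it as the initial reconstruction
for DART on the next finer grid, halving the pixel size at each switch
until the target grid is reached.

``MDART n`` uses ``n`` grids: level ``k`` (``k = n-1 ... 0``) has pixel
size ``2**k`` times the target pixel size and correspondingly fewer pixels,
always spanning the same physical field of view; the projection data is
shared untouched across all levels.  ``MDART 1`` is by construction
identical to plain DART.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dart import (
    Budget,
    DARTConfig,
    ReconstructionTrace,
    WorkTracker,
    dart_reconstruct,
    segment,
)
from .dart import GreyLevelModel
from .geometry import GeometryError, Image, ImageGrid, Sinogram, coarsen_grid
from .projector import JosephOperator


def upsample(image: Image, factor: int = 2) -> Image:
    """Bilinear upsampling by 2, preserving the physical field of view.

    Pixel values are treated as samples at pixel centers; target centers
    outside the span of source centers replicate the edge value.  The output
    grid has doubled side and halved pixel size, so the object's physical
    center is preserved.
    """
    if factor != 2:
        raise ValueError("only factor-2 upsampling is supported")
    src = image.grid
    dst = ImageGrid(src.n_rows * 2, src.n_cols * 2, src.pixel_size / 2.0)
    # target center j maps to source coordinate (j + 0.5) / 2 - 0.5
    coords = (np.arange(dst.n_cols) + 0.5) / 2.0 - 0.5
    lo = np.clip(np.floor(coords).astype(int), 0, src.n_cols - 1)
    hi = np.clip(lo + 1, 0, src.n_cols - 1)
    frac = np.clip(coords - np.floor(coords), 0.0, 1.0)
    frac[coords < 0] = 0.0
    frac[coords > src.n_cols - 1] = 0.0

    v = image.values
    rows = v[:, lo] * (1 - frac)[None, :] + v[:, hi] * frac[None, :]
    out = rows[lo, :] * (1 - frac)[:, None] + rows[hi, :] * frac[:, None]
    return Image(dst, out)


@dataclass(frozen=True)
class MDARTConfig:
    """Multiresolution schedule: grid count plus the shared DART parameters.

    ``n_levels`` grids are used; the coarsest has pixel size
    ``2**(n_levels-1)`` times the target's, so the target side must be
    divisible by that factor.  Unless ``level_overrides`` supplies a
    replacement :class:`DARTConfig` for a level index, every level runs the
    same DART parameters.
    """

    n_levels: int = 2
    dart: DARTConfig = field(default_factory=DARTConfig)
    level_overrides: dict[int, DARTConfig] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")

    def config_for(self, level: int) -> DARTConfig:
        return self.level_overrides.get(level, self.dart)


def mdart_reconstruct(
    sinogram: Sinogram,
    target_grid: ImageGrid,
    model: GreyLevelModel,
    config: MDARTConfig | None = None,
    budget: Budget | None = None,
    ground_truth: Image | None = None,
) -> tuple[Image, Image, ReconstructionTrace]:
    """Run MDART and return (continuous, segmented, trace) on the target grid.

    The initial SIRT reconstruction is computed only on the coarsest grid;
    each finer level starts from the bilinear upsampling of the previous
    level's continuous iterate.  The trace marks level switches, and a
    shared work/time budget (in target-grid SIRT-iteration equivalents)
    spans all levels.
    """
    config = config or MDARTConfig()
    n = config.n_levels
    if target_grid.n_cols % (2 ** (n - 1)) != 0:
        raise GeometryError(
            f"target grid side {target_grid.n_cols} is not divisible by 2^{n - 1}"
        )
    rng = np.random.default_rng(config.dart.rng_seed)
    tracker = WorkTracker(budget, target_grid.n_pixels)
    trace = ReconstructionTrace()
    continuous: Image | None = None
    iteration_offset = 0

    for level in range(n - 1, -1, -1):
        grid = coarsen_grid(target_grid, level)
        operator = JosephOperator(sinogram.geometry, grid)
        continuous, _, trace = dart_reconstruct(
            sinogram,
            grid,
            model,
            config.config_for(level),
            initial=continuous,
            rng=rng,
            tracker=tracker,
            trace=trace,
            level=level,
            iteration_offset=iteration_offset,
            ground_truth=ground_truth,
            operator=operator,
        )
        iteration_offset = trace.records[-1].iteration if trace.records else iteration_offset
        if level > 0:
            continuous = upsample(continuous)
        if tracker.exhausted():
            # upsample the partial result to the target grid and stop
            while continuous.grid.n_cols < target_grid.n_cols:
                continuous = upsample(continuous)
            break

    segmented = segment(continuous, model)
    return continuous, segmented, trace
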