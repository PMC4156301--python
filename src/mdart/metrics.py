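"""Segmentation-quality metrics for discrete reconstructions.

The headline figure of merit is the relative number of misclassified
pixels (RNMP): the reconstruction is resampled onto the ground-truth
phantom's grid with nearest-neighbour interpolation (so labels stay
labels), and the number of pixels whose grey value differs from the
phantom is divided by the number of phantom pixels with nonzero grey
value.  The object-size denominator is the established convention for this
error measure in the discrete-tomography literature; it is isolated in
:func:`rnmp` so an alternative normalization could be swapped in.
"""

from __future__ import annotations

import numpy as np

from .dart import GreyLevelModel, segment
from .geometry import Image, ImageGrid

#: categorical codes produced by :func:`error_image`
CORRECT_BACKGROUND = 0
CORRECT_OBJECT = 1
MISCLASSIFIED_BACKGROUND = 2  # phantom background reconstructed as object
MISCLASSIFIED_OBJECT = 3  # phantom object reconstructed as background

#: display palette (RGB): black, yellow, red, green
ERROR_PALETTE = np.array(
    [[0, 0, 0], [255, 255, 0], [255, 0, 0], [0, 255, 0]], dtype=np.uint8
)


def resample_nearest(image: Image, target_grid: ImageGrid) -> Image:
    """Nearest-neighbour resampling onto a grid with the same field of view.

    Each target pixel takes the value of the source pixel whose center is
    nearest to the target pixel's center, so no new values are created.
    """
    src = image.grid
    if not np.isclose(src.extent, target_grid.extent):
        raise ValueError(
            f"field of view mismatch: source {src.extent:g}, target {target_grid.extent:g}"
        )
    if src.shape == target_grid.shape:
        return image.copy()
    n_s, n_t = src.n_cols, target_grid.n_cols
    # target center j sits at fraction (j + 0.5) / n_t of the extent
    idx = np.floor((np.arange(n_t) + 0.5) * n_s / n_t).astype(int)
    idx = np.clip(idx, 0, n_s - 1)
    return Image(target_grid, image.values[np.ix_(idx, idx)])


def rnmp(phantom: Image, reconstruction: Image, model: GreyLevelModel | None = None) -> float:
    """Relative number of misclassified pixels against a phantom.

    The reconstruction is brought onto the phantom's grid by
    nearest-neighbour resampling; if a grey-level ``model`` is given both
    images are segmented with it first.  The denominator is the number of
    phantom pixels with nonzero grey value.
    """
    recon = resample_nearest(reconstruction, phantom.grid)
    if model is not None:
        phantom = segment(phantom, model)
        recon = segment(recon, model)
    object_pixels = int(np.count_nonzero(phantom.values))
    if object_pixels == 0:
        raise ValueError("RNMP is undefined for an all-background phantom")
    mismatches = int(np.count_nonzero(recon.values != phantom.values))
    return mismatches / object_pixels


def error_image(phantom: Image, reconstruction: Image) -> Image:
    """Four-way classification map of a segmented reconstruction.

    Categories: correct background (0), correct object (1), misclassified
    background (2: background reconstructed as object) and misclassified
    object (3: object reconstructed as background or as the wrong material).
    """
    recon = resample_nearest(reconstruction, phantom.grid)
    ph_obj = phantom.values != 0
    correct = recon.values == phantom.values
    codes = np.empty(phantom.grid.shape, dtype=float)
    codes[~ph_obj & correct] = CORRECT_BACKGROUND
    codes[ph_obj & correct] = CORRECT_OBJECT
    codes[~ph_obj & ~correct] = MISCLASSIFIED_BACKGROUND
    codes[ph_obj & ~correct] = MISCLASSIFIED_OBJECT
    return Image(phantom.grid, codes)


def error_image_rgb(codes: Image) -> np.ndarray:
    """Render an error map as an RGB array with the conventional palette."""
    return ERROR_PALETTE[codes.values.astype(int)]
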