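"""SIRT: simultaneous iterative reconstruction with optional pixel masking.

The update is ``x <- x + relaxation * C W^T R (p - W x)`` where ``R`` and
``C`` hold the reciprocals of the projector's per-ray and per-pixel weight
sums.  Rays that miss the grid and pixels touched by no ray get a zero
reciprocal and are silently inert.

When a mask of non-fixed pixels is supplied, the update is applied to the
masked pixels only; all other pixels keep their exact input values.  The
frozen pixels still contribute fully to ``W x``, so the residual seen by the
free pixels accounts for the fixed material — this is the masked-update
behaviour the DART loop relies on.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .geometry import Image, Sinogram
from .projector import JosephOperator


def _safe_reciprocal(a: np.ndarray) -> np.ndarray:
    out = np.zeros_like(a, dtype=float)
    nz = a != 0
    out[nz] = 1.0 / a[nz]
    return out


class SIRTSolver:
    """Reusable SIRT iteration state bound to one operator and sinogram."""

    def __init__(self, operator: JosephOperator, sinogram: Sinogram):
        expected = (operator.geometry.n_angles, operator.geometry.n_detectors)
        if sinogram.values.shape != expected:
            raise ValueError("sinogram does not match the operator geometry")
        self.operator = operator
        self.sinogram = sinogram
        self.inv_row_sums = _safe_reciprocal(operator.row_sums())
        self.inv_col_sums = _safe_reciprocal(operator.col_sums())

    def iterate(
        self,
        values: np.ndarray,
        n_iters: int,
        mask: np.ndarray | None = None,
        relaxation: float = 1.0,
        callback: Callable[[int, np.ndarray], None] | None = None,
    ) -> np.ndarray:
        """Run ``n_iters`` updates starting from ``values``; returns a new array.

        ``mask`` is a boolean array over the grid marking the non-fixed
        pixels; ``None`` updates everything.
        """
        if n_iters < 0:
            raise ValueError("n_iters must be >= 0")
        x = np.array(values, dtype=float, copy=True)
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != x.shape:
                raise ValueError("mask shape does not match the image")
            if not mask.any():
                return x  # everything fixed: nothing to do
        p = self.sinogram.values
        for k in range(n_iters):
            residual = p - self.operator.apply(x)
            update = relaxation * self.inv_col_sums * self.operator.adjoint(
                self.inv_row_sums * residual
            )
            if not np.all(np.isfinite(update)):
                raise FloatingPointError(f"non-finite SIRT update at iteration {k}")
            if mask is None:
                x += update
            else:
                x[mask] += update[mask]
            if callback is not None:
                callback(k, x)
        return x


def sirt_run(
    initial: Image,
    sinogram: Sinogram,
    n_iters: int,
    mask: np.ndarray | None = None,
    relaxation: float = 1.0,
    operator: JosephOperator | None = None,
) -> Image:
    """Run SIRT for ``n_iters`` iterations from an initial image.

    Convenience wrapper around :class:`SIRTSolver`; pass a prebuilt
    ``operator`` to amortize weight assembly across calls.
    """
    if operator is None:
        operator = JosephOperator(sinogram.geometry, initial.grid)
    solver = SIRTSolver(operator, sinogram)
    return Image(initial.grid, solver.iterate(initial.values, n_iters, mask, relaxation))


def projection_distance(
    image: Image, sinogram: Sinogram, operator: JosephOperator | None = None
) -> float:
    """Euclidean norm of the projection residual ``||W x - p||``."""
    if operator is None:
        operator = JosephOperator(sinogram.geometry, image.grid)
    return float(np.linalg.norm(operator.apply(image.values) - sinogram.values))
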