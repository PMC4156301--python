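"""Poisson photon noise for transmission sinograms.

Noise is applied in the count (transmission) domain: for a clean line
integral ``p`` the expected detected photon count is ``I0 * exp(-p)``,
a Poisson draw replaces it, and the noisy integral is recovered as
``-ln(N / I0)``.  Zero counts are clamped to one photon before the log so
the noisy integral stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Sinogram


@dataclass(frozen=True)
class NoiseSpec:
    """Photon budget: expected unattenuated photons per detector bin."""

    photon_count: float
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.photon_count > 0):
            raise ValueError("photon_count must be positive")


def apply_poisson(sinogram: Sinogram, spec: NoiseSpec) -> Sinogram:
    """Poisson-degrade a sinogram of nonnegative line integrals.

    Reproducible from ``spec.rng_seed``.  Raises if the input contains
    negative values, which have no transmission interpretation.
    """
    p = sinogram.values
    if np.any(p < 0):
        raise ValueError("line integrals must be nonnegative for photon noise")
    rng = np.random.default_rng(spec.rng_seed)
    lam = spec.photon_count * np.exp(-p)
    counts = rng.poisson(lam).astype(float)
    counts = np.maximum(counts, 1.0)
    noisy = -np.log(counts / spec.photon_count)
    return Sinogram(sinogram.geometry, noisy)


def noisy_replicates(sinogram: Sinogram, spec: NoiseSpec, n_reps: int) -> list[Sinogram]:
    """Independent noisy copies using sequential seeds ``seed, seed+1, ...``."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    return [
        apply_poisson(sinogram, NoiseSpec(spec.photon_count, spec.rng_seed + i))
        for i in range(n_reps)
    ]
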