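# mdart — multiresolution discrete algebraic tomographic reconstruction

In discrete tomography the scanned object is assumed to consist of a small
number of materials with known attenuation values. The Discrete Algebraic
Reconstruction Technique (DART) exploits this prior to reconstruct objects
from far fewer projections than conventional methods need: it alternates a
few masked SIRT iterations on "free" pixels with a global-threshold
segmentation that pins confidently classified pixels to their material
values. Its weakness is slow convergence when the data is very limited —
few views or a missing wedge make the initial algebraic reconstruction so
artefact-ridden that many DART iterations are spent undoing it.

This package implements the coarse-to-fine remedy, **multiresolution DART
(MDART)**, together with everything needed to study it in simulation: a
Joseph ray-driven projector for parallel and equiangular fan beams (with
missing-wedge support), masked SIRT, the DART loop, phantom generators,
a Poisson photon-noise model, evaluation metrics and a benchmark runner.
It is aimed at researchers in tomographic image reconstruction who want a
compact, fully reproducible CPU reference implementation.

## The algorithms

The reconstruction problem is the linear system `W x = p`, where `p` holds
the measured line integrals (the sinogram), `x` the unknown pixel values
and `W` the projection matrix (Joseph interpolation weights). SIRT iterates

    x ← x + C Wᵀ R (p − W x)

with `R` and `C` the diagonal inverse row/column sums of `W`. DART embeds
this update in a segment → partition → masked-update → smooth loop: after
segmenting the current iterate with thresholds `τ_i` between the material
grey values `ρ_1 < … < ρ_L`, the non-fixed set `U` consists of the boundary
pixels (those with a differently labelled neighbour) plus a random fraction
`p` of the rest; fixed pixels are held at their material values while SIRT
updates only `U`.

`MDART n` runs this on `n` grids. The coarsest grid has pixel size
`2^(n−1)` times the target's (same physical field of view), which makes
the few-view system far less underdetermined; each finer level starts from
the bilinear upsampling of the previous level's continuous iterate, halving
the pixel size at every switch. `MDART 1` is exactly plain DART. Quality is
measured by the relative number of misclassified pixels (RNMP):
misclassified pixel count after nearest-neighbour resampling onto the
ground-truth grid, divided by the number of ground-truth object pixels.

## Worked example

```python
from mdart import (DARTConfig, GreyLevelModel, ImageGrid, dart_reconstruct,
                   default_geometry, disk_with_holes, forward_project, rnmp)

grid = ImageGrid(64, 64, 1.0)
phantom = disk_with_holes(64, disk_radius=24, hole_radius=5, n_holes=3, seed=0)
geometry = default_geometry(grid, 15, "fan")          # 15 views over 360°
sinogram = forward_project(phantom, geometry)          # noiseless data
model = GreyLevelModel((0.0, 1.0))                     # binary material prior

cont, seg, trace = dart_reconstruct(sinogram, grid, model,
                                    DARTConfig(rng_seed=0),
                                    ground_truth=phantom)
print(f"DART stopped after {len(trace)} iterations")
print(f"final RNMP: {rnmp(phantom, seg, model):.4f}")
```

prints

```
DART stopped after 16 iterations
final RNMP: 0.0000
```

i.e. the binary disk with three holes is recovered **exactly** from only
15 fan-beam projections. Under harder conditions — 8 views, a 30° missing
wedge, small holes, and a fixed work budget of 280 target-grid
SIRT-iteration equivalents shared by all algorithms — the multiresolution
schedule pays off:

```
SSIRT   RNMP = 0.0843
DART    RNMP = 0.0432
MDART2  RNMP = 0.0362
```

Segmented SIRT leaves heavy streak artefacts, single-grid DART is still
mid-convergence when the budget runs out, and two-level MDART has already
reached the pixelation floor of the comparison (~0.039 for this phantom).

The same pipeline is available from the shell:

```bash
mdart phantom --kind disk_with_holes --size 64 --out phantom.png
mdart project --image phantom.png --n-angles 15 --beam fan --out sino.raw
mdart reconstruct --sinogram sino.raw --algorithm mdart --levels 2 \
      --grid-size 64 --pixel-size 1.0 --out recon.png
mdart evaluate --phantom phantom.png --reconstruction recon.png
```

## Layout

- `mdart.geometry`, `mdart.io` — grids, images, geometries, sinograms, file I/O
- `mdart.projector` — Joseph forward/back projector and test oracle
- `mdart.sirt` — (masked) SIRT and the projection distance
- `mdart.dart` — grey-level model, segmentation, partitioning, the DART loop
- `mdart.multires` — bilinear upsampling and the MDART driver
- `mdart.phantoms`, `mdart.noise` — test objects and Poisson photon noise
- `mdart.metrics`, `mdart.experiments` — RNMP, error maps, benchmark sweeps
- `mdart.cli` — the `mdart` command

See `docs/methods.md` for the modelling assumptions, parameter defaults and
numerical conventions.
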