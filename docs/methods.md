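# Methods

This note documents the models, conventions and defaults behind the
package, the choices made where the design was genuinely open, and what
the simulation results do and do not demonstrate.

## Coordinate and acquisition model

World coordinates are centered on the rotation axis, x right, y up, angles
counter-clockwise from the x-axis. The reconstruction grid is square,
centered on the axis, with a physical pixel size; the field of view
(side × pixel size) is an invariant preserved by every resolution change.
Projection angles are equiangular on the half-open interval
`[0, range − wedge)` so that n views over 180° never duplicate the 0/180
pair. A missing wedge is removed from the top of the range; since the
phantom orientation is arbitrary, any contiguous wedge placement is
equivalent up to a rotation of the object. Fan beams are modelled as a
point source at distance `d_so` from the axis and a flat detector at
`d_sd` from the source; rays run from the source through each detector
bin center (one ray per bin; supersampling was considered and left out —
single-ray bins are the common choice and the evaluation metric is
segmentation-based, so sub-bin quadrature has no visible effect at the
scales used here).

## Projector

Joseph's method: each ray marches along its dominant axis one row/column
at a time, linearly interpolating the image between the two adjacent pixel
centers on the minor axis, with a per-step path-length factor
`pixel_size / |d_major|`. Interpolation partners outside the grid are
dropped; rays missing the grid contribute zero and their inverse row sum
is defined as zero, so they are inert in SIRT.

The interpolation weights depend only on the (geometry, grid) pair, so the
operator assembles them once into a sparse matrix and reuses it. This
keeps every SIRT iteration a sparse matrix-vector product and makes back
projection the exact transpose of forward projection — the adjoint
identity holds to floating-point round-off by construction rather than by
approximation. A dense materialization exists only for grids of side ≤ 16
(testing); at desk scale the sparse weights for a 256×256 grid with ~60
views occupy tens of megabytes.

Two independent oracles validate the projector. A nearest-pixel dense
sampling integral checks absolute values against the piecewise-constant
image model; a bilinear dense sampling integral checks the Joseph
quadrature against its own (interpolated) image model. The two image
models genuinely differ on rough images — per-ray agreement at the 1%
level requires fields that are smooth at a several-pixel scale and carry
negligible mass at the grid border, which is what the test fields use.
This is a property of the discretizations, not an implementation error:
against the bilinear oracle the projector agrees to better than 0.1% per
ray.

## SIRT

The update `x ← x + λ C Wᵀ R (p − W x)` with relaxation λ = 1 by default
(no relaxation and no non-negativity clipping are applied unless
requested; both are exposed as configuration). Zero row/column sums invert
to zero. On consistent systems the iteration converges to the row-weighted
least-squares solution; this is verified in the tests against a direct
dense solve, to machine precision at large iteration counts. Convergence
speed depends on detector sampling: the tiny 8×8 reference system uses
half-pixel detector bins, where 500 iterations suffice for ~1e-9 relative
accuracy (with one-pixel bins the same accuracy needs ~4× the iterations).

Masked SIRT applies the update to the non-fixed pixels only; fixed pixels
keep their exact input values bitwise but contribute fully to `W x`, so
the residual seen by the free pixels accounts for the fixed material.

## DART

Per iteration: segment → partition → masked SIRT → termination check →
smooth, with smoothing skipped after the terminating iteration so the
returned image is the un-smoothed post-update iterate. Defaults, all
configurable:

- initial SIRT iterations: 200; inner SIRT iterations per DART iteration: 10.
- random free fraction p = 0.15 of non-boundary pixels, redrawn each
  iteration from one seeded stream (a fresh draw per iteration lets new
  boundaries form anywhere; the alternative of a one-off draw would bias
  later iterations toward the first sample).
- boundary connectivity 8 (stricter boundary set; 4 available).
- smoothing: each pixel blended with the mean of its in-grid 3×3
  neighbourhood (excluding itself) with weight b = 0.1, applied to the
  whole image — not only to boundary pixels, as some variants do.
- segmentation thresholds default to grey-value midpoints; values exactly
  on a threshold go to the lower class (ties have measure zero on real data).
- termination: change in projection distance ‖Wx − p‖ below 1e-4 of the
  sinogram norm for 3 consecutive iterations (patience 3); iteration-count
  and modified-pixel-fraction criteria are also available.

## MDART

`MDART n` uses n grids; level k has pixel size `2^k` × target and side
`/2^k`, so the target side must be divisible by `2^(n−1)`. The initial
SIRT reconstruction is computed only on the coarsest grid; every finer
level starts from the bilinear upsampling of the previous continuous
iterate — that reuse is the entire mechanism of the speed-up. Upsampling
treats pixel values as samples at pixel centers with edge replication, so
the object's physical center is preserved; the continuous iterate is
upsampled, never the segmentation (interpolated labels would leave the
grey-value set). All levels share the untouched sinogram and geometry,
the same DART parameters (per-level overrides possible) and the same
termination rule. With n = 1 the driver reduces bitwise to plain DART.

## Work accounting and budgets

Benchmarks stop algorithms after a fixed budget. Besides wall time, the
package offers a hardware-independent unit: one SIRT iteration on a grid
with m pixels costs `m / m_target` work units, so one coarse-level
iteration at level k costs `4^−k` of a target-level iteration. Budgets are
checked between DART iterations only, never mid-SIRT, so iteration counts
are reproducible. The equal-budget comparisons in the tests and the
acceptance script use 280 units — 1.4× the cost of the 200-iteration
initial reconstruction, which places single-grid DART mid-convergence on
the few-view problems, the regime the multiresolution schedule targets.

## Phantoms and noise

Phantoms are rasterized by a pixel-center membership rule with no
anti-aliasing, so they contain exactly their declared grey values — the
discrete prior holds exactly. The families: a disk with randomly placed
non-overlapping holes (rejection sampling, hard cap of 10,000 attempts
with an explicit packing error), a Siemens star of alternating sectors, a
multi-grey composite of intersecting ellipses, and a synthetic
structured-binary composition of rectangles/disks/annuli standing in for
machined-part-style objects. Ground-truth phantoms are generated at twice
the reconstruction resolution by default (same field of view), so the
evaluation is not dominated by the pixelation of the truth itself; the
projector consumes the fine phantom directly. The resulting resampling
floor (RNMP of a perfect reconstruction) is ~0.04 for the 64-px disk
problems used in the tests — reported RNMPs must be read against it.

Photon noise acts in the transmission domain: expected counts
`λ = I₀ exp(−p)` per bin, Poisson draw, log transform back; zero counts
are clamped to one photon so integrals stay finite. This requires line
integrals of order unity to be physically meaningful, so noise experiments
scale the binary phantom's attenuation to 0.04 per pixel (max integral
≈ 2). Replicates use sequential seeds from the base seed.

## Evaluation

RNMP = misclassified pixels / ground-truth object pixels, after
nearest-neighbour resampling of the reconstruction onto the truth's grid
(labels stay labels). The object-pixel denominator is the established
convention for this measure; it is isolated in `mdart.metrics.rnmp` so it
could be swapped. Error maps classify pixels into correct/misclassified ×
background/object with the conventional black/yellow/red/green palette;
for multi-grey phantoms "object" means any nonzero grey value and a wrong
material counts as a misclassified object pixel.

## Scope of the simulation evidence

The synthetic study emulates few-view and missing-wedge acquisition with
exact grey-value priors and ideal detectors. It does not model detector
blur, beam hardening, scatter, cone-beam geometry or grey-value estimation
from data — conclusions from passing tests therefore concern algorithmic
behaviour (convergence, masking contracts, multiresolution benefit and its
sub-pixel-feature failure mode), not end-to-end performance on real
scanner data. Problem sizes in the tests (grids of side 8–64, ≤ 15 views,
10 seeded trials) were chosen as the smallest at which these effects are
clearly expressed.

## Known limitations

- Only square grids and dyadic level ratios; no per-level sinogram rebinning.
- Fan-beam rays carry path length only (no distance weighting), detector
  offsets/tilts are not modelled.
- SIRT is the only algebraic backend; the solver interface is internal, so
  alternatives (ART, CGLS) could be added but none ship.
- Wall-time entries in traces are inherently non-reproducible; all other
  trace columns and all outputs are bitwise deterministic per seed on one
  platform.
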