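"""DART: discrete algebraic reconstruction by alternating update and segmentation.

The discrete-tomography prior is that the object consists of a small number
of materials with known attenuation values.  DART exploits it by iterating:

1. segment the current continuous reconstruction with global thresholds;
2. partition the pixels: boundary pixels (those with a differently
   segmented neighbour) plus a random fraction of the remaining pixels form
   the non-fixed set, everything else is fixed at its segmented grey value;
3. run a few masked SIRT iterations that update only the non-fixed pixels;
4. check the termination criterion; if not met, smooth the whole continuous
   iterate and repeat.

Confidently classified interior pixels are thereby pinned to their material
values, which drastically reduces the number of unknowns the algebraic
solver has to determine from few projections.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import Image, ImageGrid, Sinogram
from .projector import JosephOperator
from .sirt import SIRTSolver


# ---------------------------------------------------------------------------
# grey-level model and segmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GreyLevelModel:
    """Ordered material grey values with global segmentation thresholds.

    ``thresholds[i]`` separates ``grey_values[i]`` from ``grey_values[i+1]``;
    by default each threshold is the midpoint of its neighbouring grey
    values.  Values exactly on a threshold are assigned to the lower class.
    """

    grey_values: tuple[float, ...]
    thresholds: tuple[float, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        greys = tuple(float(g) for g in self.grey_values)
        if len(greys) < 2:
            raise ValueError("a grey-level model needs at least two grey values")
        if not all(a < b for a, b in zip(greys, greys[1:])):
            raise ValueError("grey values must be strictly increasing")
        if self.thresholds is None:
            thr = tuple((a + b) / 2.0 for a, b in zip(greys, greys[1:]))
        else:
            thr = tuple(float(t) for t in self.thresholds)
        if len(thr) != len(greys) - 1:
            raise ValueError("need exactly one threshold between consecutive grey values")
        for i, t in enumerate(thr):
            if not (greys[i] < t < greys[i + 1]):
                raise ValueError(
                    f"threshold {t} must lie strictly between grey values "
                    f"{greys[i]} and {greys[i + 1]}"
                )
        object.__setattr__(self, "grey_values", greys)
        object.__setattr__(self, "thresholds", thr)

    @property
    def n_levels(self) -> int:
        return len(self.grey_values)


def segment(image: Image, model: GreyLevelModel) -> Image:
    """Global-threshold segmentation onto the model's grey values."""
    greys = np.asarray(model.grey_values)
    thr = np.asarray(model.thresholds)
    # count of thresholds strictly below each value: ties go to the lower class
    idx = np.searchsorted(thr, image.values, side="left")
    return Image(image.grid, greys[idx])


# ---------------------------------------------------------------------------
# pixel partition
# ---------------------------------------------------------------------------

_SHIFTS_4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_SHIFTS_8 = _SHIFTS_4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def boundary_pixels(segmented: Image, connectivity: int = 8) -> np.ndarray:
    """Boolean mask of pixels with at least one differing neighbour.

    Neighbourhoods are 4- or 8-connected; border pixels use in-grid
    neighbours only.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    v = segmented.values
    n0, n1 = v.shape
    out = np.zeros(v.shape, dtype=bool)
    shifts = _SHIFTS_4 if connectivity == 4 else _SHIFTS_8
    for dr, dc in shifts:
        # pixels (r, c) whose neighbour (r+dr, c+dc) lies in the grid
        r0, r1 = max(-dr, 0), n0 + min(-dr, 0)
        c0, c1 = max(-dc, 0), n1 + min(-dc, 0)
        center = v[r0:r1, c0:c1]
        neighbour = v[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        out[r0:r1, c0:c1] |= center != neighbour
    return out


@dataclass
class PixelPartition:
    """Fixed/non-fixed pixel sets driving the masked SIRT update."""

    non_fixed: np.ndarray  # boolean mask U
    boundary: np.ndarray  # boolean mask B, subset of U

    @property
    def fixed(self) -> np.ndarray:
        return ~self.non_fixed


def make_partition(
    segmented: Image,
    fix_probability: float,
    rng: np.random.Generator,
    connectivity: int = 8,
) -> PixelPartition:
    """Boundary pixels plus an independent random sample of the rest.

    Each non-boundary pixel joins the non-fixed set independently with
    probability ``fix_probability``, allowing new boundaries to form away
    from the current segmentation edges.
    """
    if not (0.0 <= fix_probability <= 1.0):
        raise ValueError("fix_probability must lie in [0, 1]")
    boundary = boundary_pixels(segmented, connectivity)
    random_free = rng.random(boundary.shape) < fix_probability
    non_fixed = boundary | (random_free & ~boundary)
    return PixelPartition(non_fixed=non_fixed, boundary=boundary)


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------


def smooth(image: Image, blend: float) -> Image:
    """Blend each pixel with the mean of its in-grid 3x3 neighbours.

    ``x <- (1 - b) x + b mean(neighbours)`` where the neighbourhood excludes
    the pixel itself and is clipped at the image border.
    """
    if not (0.0 <= blend <= 1.0):
        raise ValueError("blend must lie in [0, 1]")
    if blend == 0.0:
        return image.copy()
    v = image.values
    padded = np.pad(v, 1, mode="constant")
    window = (
        padded[:-2, :-2] + padded[:-2, 1:-1] + padded[:-2, 2:]
        + padded[1:-1, :-2] + padded[1:-1, 2:]
        + padded[2:, :-2] + padded[2:, 1:-1] + padded[2:, 2:]
    )
    counts = np.full(v.shape, 8.0)
    counts[0, :] -= 3
    counts[-1, :] -= 3
    counts[:, 0] -= 3
    counts[:, -1] -= 3
    counts[0, 0] += 1  # corners lost 5 neighbours, not 6
    counts[0, -1] += 1
    counts[-1, 0] += 1
    counts[-1, -1] += 1
    neighbour_mean = window / counts
    return Image(image.grid, (1.0 - blend) * v + blend * neighbour_mean)


# ---------------------------------------------------------------------------
# termination and budgets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TerminationSpec:
    """When to stop the DART outer loop.

    kind:
        ``max_iterations`` — stop once the iteration count reaches
        ``threshold``;
        ``modified_pixels`` — stop when the fraction of pixels whose
        segmentation changed stays below ``threshold`` for ``patience``
        consecutive iterations;
        ``projection_distance_delta`` — stop when the absolute change of the
        projection distance between consecutive iterations stays below
        ``threshold`` for ``patience`` consecutive iterations.  With
        ``relative=True`` the threshold is scaled by the sinogram norm.
    """

    kind: str = "projection_distance_delta"
    threshold: float = 1e-4
    patience: int = 3
    relative: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("max_iterations", "modified_pixels", "projection_distance_delta"):
            raise ValueError(f"unknown termination kind {self.kind!r}")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TraceRecord:
    """One DART iteration's worth of diagnostics."""

    iteration: int
    level: int
    time_s: float
    proj_distance: float
    modified_pixels: int
    modified_fraction: float
    work_units: float
    level_switch: bool = False
    rnmp: float | None = None


@dataclass
class ReconstructionTrace:
    """Per-iteration records accumulated over a (multi-level) reconstruction."""

    records: list[TraceRecord] = field(default_factory=list)

    def append(self, record: TraceRecord) -> None:
        if self.records and record.iteration <= self.records[-1].iteration:
            raise ValueError("trace iterations must be strictly increasing")
        self.records.append(record)

    def __len__(self) -> int:
        return len(self.records)

    def for_level(self, level: int) -> "ReconstructionTrace":
        return ReconstructionTrace([r for r in self.records if r.level == level])

    @property
    def n_level_switches(self) -> int:
        return sum(r.level_switch for r in self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def check_termination(
    trace: ReconstructionTrace, spec: TerminationSpec, sinogram_norm: float = 1.0
) -> bool:
    """Evaluate a termination criterion on the (current level's) trace."""
    records = trace.records
    if not records:
        raise ValueError("termination check requires a non-empty trace")
    if spec.kind == "max_iterations":
        return len(records) >= spec.threshold
    if spec.kind == "modified_pixels":
        if len(records) < spec.patience:
            return False
        recent = records[-spec.patience :]
        return all(r.modified_fraction < spec.threshold for r in recent)
    # projection_distance_delta
    if len(records) < spec.patience + 1:
        return False
    thr = spec.threshold * (sinogram_norm if spec.relative else 1.0)
    dists = [r.proj_distance for r in records[-(spec.patience + 1) :]]
    deltas = [abs(b - a) for a, b in zip(dists, dists[1:])]
    return all(d < thr for d in deltas)


@dataclass
class Budget:
    """Global stopping budget, checked between DART iterations only.

    ``max_work`` counts SIRT-iteration equivalents at a reference grid: one
    SIRT iteration on a grid with ``m`` pixels costs ``m / reference_pixels``
    units, so coarse-grid iterations are proportionally cheaper.  This gives
    a hardware-independent analogue of the wall-time budgets used when
    benchmarking; ``max_seconds`` is also available.
    """

    max_work: float | None = None
    max_seconds: float | None = None
    reference_pixels: int | None = None

    def __post_init__(self) -> None:
        for v in (self.max_work, self.max_seconds):
            if v is not None and v <= 0:
                raise ValueError("budget limits must be positive")


class WorkTracker:
    """Accumulates work units and wall time against a :class:`Budget`."""

    def __init__(self, budget: Budget | None, reference_pixels: int):
        self.budget = budget
        self.reference_pixels = (
            budget.reference_pixels if budget and budget.reference_pixels else reference_pixels
        )
        self.used_work = 0.0
        self.start = time.perf_counter()

    def charge(self, n_iters: int, n_pixels: int) -> None:
        self.used_work += n_iters * (n_pixels / self.reference_pixels)

    @property
    def elapsed(self) -> float:
        return time.perf_counter() - self.start

    def exhausted(self) -> bool:
        if self.budget is None:
            return False
        if self.budget.max_work is not None and self.used_work >= self.budget.max_work:
            return True
        if self.budget.max_seconds is not None and self.elapsed >= self.budget.max_seconds:
            return True
        return False


# ---------------------------------------------------------------------------
# the DART loop
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DARTConfig:
    """Tunable parameters of the DART loop.

    ``initial_arm_iters`` unmasked SIRT iterations build the starting
    reconstruction; each DART iteration then applies ``inner_arm_iters``
    masked SIRT iterations to the non-fixed pixels.  ``fix_probability`` is
    the chance for a non-boundary pixel to be freed anyway, and
    ``smoothing_blend`` the weight of the 3x3 neighbour mean mixed into the
    iterate between DART iterations.
    """

    initial_arm_iters: int = 200
    inner_arm_iters: int = 10
    fix_probability: float = 0.15
    smoothing_blend: float = 0.1
    termination: TerminationSpec = field(default_factory=TerminationSpec)
    rng_seed: int = 0
    connectivity: int = 8
    relaxation: float = 1.0
    max_dart_iterations: int = 1000

    def __post_init__(self) -> None:
        if self.initial_arm_iters < 0 or self.inner_arm_iters < 0:
            raise ValueError("iteration counts must be >= 0")
        if not (0.0 <= self.fix_probability <= 1.0):
            raise ValueError("fix_probability must lie in [0, 1]")
        if not (0.0 <= self.smoothing_blend <= 1.0):
            raise ValueError("smoothing_blend must lie in [0, 1]")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def dart_reconstruct(
    sinogram: Sinogram,
    grid: ImageGrid,
    model: GreyLevelModel,
    config: DARTConfig | None = None,
    initial: Image | None = None,
    budget: Budget | None = None,
    *,
    rng: np.random.Generator | None = None,
    tracker: WorkTracker | None = None,
    trace: ReconstructionTrace | None = None,
    level: int = 0,
    iteration_offset: int = 0,
    ground_truth: Image | None = None,
    operator: JosephOperator | None = None,
) -> tuple[Image, Image, ReconstructionTrace]:
    """Run the DART loop and return (continuous, segmented, trace).

    If ``initial`` is omitted, the starting point is
    ``config.initial_arm_iters`` unmasked SIRT iterations from zero.  The
    run is deterministic given ``config.rng_seed``.  The keyword-only
    arguments let the multiresolution driver thread a shared random stream,
    work tracker and trace through several per-level DART runs; ordinary
    callers can ignore them.
    """
    config = config or DARTConfig()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    if operator is None:
        operator = JosephOperator(sinogram.geometry, grid)
    solver = SIRTSolver(operator, sinogram)
    if tracker is None:
        tracker = WorkTracker(budget, grid.n_pixels)
    if trace is None:
        trace = ReconstructionTrace()
    sino_norm = sinogram.norm()

    if initial is None:
        x = solver.iterate(np.zeros(grid.shape), config.initial_arm_iters,
                           relaxation=config.relaxation)
        tracker.charge(config.initial_arm_iters, grid.n_pixels)
    else:
        if initial.grid != grid:
            raise ValueError("initial image grid does not match the reconstruction grid")
        x = initial.values.copy()

    prev_seg = segment(Image(grid, x), model).values
    first_record = True

    for it in range(1, config.max_dart_iterations + 1):
        if tracker.exhausted():
            break
        seg = segment(Image(grid, x), model).values
        partition = make_partition(
            Image(grid, seg), config.fix_probability, rng, config.connectivity
        )
        # fixed pixels take their material values; free pixels keep the
        # continuous estimate
        x = np.where(partition.fixed, seg, x)
        x = solver.iterate(
            x, config.inner_arm_iters, mask=partition.non_fixed,
            relaxation=config.relaxation,
        )
        tracker.charge(config.inner_arm_iters, grid.n_pixels)

        new_seg = segment(Image(grid, x), model).values
        modified = int(np.count_nonzero(new_seg != prev_seg))
        prev_seg = new_seg
        dist = float(np.linalg.norm(operator.apply(x) - sinogram.values))
        record = TraceRecord(
            iteration=iteration_offset + it,
            level=level,
            time_s=tracker.elapsed,
            proj_distance=dist,
            modified_pixels=modified,
            modified_fraction=modified / grid.n_pixels,
            work_units=tracker.used_work,
            level_switch=first_record and iteration_offset > 0,
        )
        if ground_truth is not None:
            from .metrics import rnmp  # local import to avoid a cycle

            record.rnmp = rnmp(ground_truth, Image(grid, new_seg), model)
        trace.append(record)
        first_record = False

        if check_termination(trace.for_level(level), config.termination, sino_norm):
            break
        if tracker.exhausted():
            break
        x = smooth(Image(grid, x), config.smoothing_blend).values

    continuous = Image(grid, x)
    segmented = segment(continuous, model)
    return continuous, segmented, trace
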