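"""DART building blocks and the full reconstruction loop."""

import numpy as np
import pytest

from mdart import (
    Budget,
    DARTConfig,
    GreyLevelModel,
    Image,
    ImageGrid,
    ReconstructionTrace,
    TerminationSpec,
    TraceRecord,
    boundary_pixels,
    check_termination,
    dart_reconstruct,
    make_partition,
    rnmp,
    segment,
    smooth,
)


class TestGreyLevelModel:
    def test_default_thresholds_are_midpoints(self):
        model = GreyLevelModel((0.0, 1.0, 3.0))
        assert model.thresholds == (0.5, 2.0)

    def test_threshold_outside_interval_rejected(self):
        with pytest.raises(ValueError, match="between"):
            GreyLevelModel((0.0, 1.0), thresholds=(1.5,))

    def test_needs_two_levels(self):
        with pytest.raises(ValueError):
            GreyLevelModel((1.0,))


class TestSegment:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.0, 0.0), (0.7, 1.0), (0.5, 0.0), (1.0, 1.0), (-2.0, 0.0), (9.0, 1.0)],
    )
    def test_binary_thresholding(self, value, expected):
        model = GreyLevelModel((0.0, 1.0))
        img = Image(ImageGrid(2, 2), np.full((2, 2), value))
        assert segment(img, model).values[0, 0] == expected

    def test_three_level_interval_lookup(self):
        model = GreyLevelModel((0.0, 0.5, 1.0), thresholds=(0.25, 0.75))
        img = Image(ImageGrid(2, 2), np.array([[0.3, 0.8], [0.25, 0.1]]))
        np.testing.assert_array_equal(
            segment(img, model).values, [[0.5, 1.0], [0.0, 0.0]]
        )

    def test_output_contains_only_model_values(self):
        model = GreyLevelModel((0.0, 0.4, 1.0))
        img = Image(ImageGrid(8, 8), np.random.default_rng(0).random((8, 8)) * 2 - 0.5)
        out = segment(img, model)
        assert set(np.unique(out.values)) <= set(model.grey_values)


class TestBoundaryPixels:
    def test_constant_image_has_no_boundary(self):
        img = Image(ImageGrid(8, 8), np.ones((8, 8)))
        assert not boundary_pixels(img).any()

    def test_single_foreground_pixel_8conn(self):
        vals = np.zeros((8, 8))
        vals[3, 4] = 1.0
        mask = boundary_pixels(Image(ImageGrid(8, 8), vals), connectivity=8)
        assert mask.sum() == 9
        assert mask[2:5, 3:6].all()

    def test_halfplane_edge_4conn(self):
        vals = np.zeros((8, 8))
        vals[:, 4:] = 1.0
        mask = boundary_pixels(Image(ImageGrid(8, 8), vals), connectivity=4)
        expected = np.zeros((8, 8), dtype=bool)
        expected[:, 3:5] = True
        np.testing.assert_array_equal(mask, expected)

    def test_4conn_is_subset_of_8conn(self):
        rng = np.random.default_rng(2)
        img = Image(ImageGrid(16, 16), (rng.random((16, 16)) > 0.5).astype(float))
        b4 = boundary_pixels(img, 4)
        b8 = boundary_pixels(img, 8)
        assert np.all(b8 | ~b4)


class TestMakePartition:
    def test_p0_gives_exactly_boundary(self):
        vals = np.zeros((16, 16))
        vals[4:12, 4:12] = 1.0
        img = Image(ImageGrid(16, 16), vals)
        part = make_partition(img, 0.0, np.random.default_rng(0))
        np.testing.assert_array_equal(part.non_fixed, boundary_pixels(img))

    def test_p1_frees_everything(self):
        img = Image(ImageGrid(8, 8), np.zeros((8, 8)))
        part = make_partition(img, 1.0, np.random.default_rng(0))
        assert part.non_fixed.all() and not part.fixed.any()

    def test_random_fraction_binomial(self):
        img = Image(ImageGrid(100, 100), np.zeros((100, 100)))
        sizes = [
            make_partition(img, 0.15, np.random.default_rng(s)).non_fixed.sum()
            for s in range(20)
        ]
        mean, sigma = 1500.0, np.sqrt(10000 * 0.15 * 0.85 / 20)
        assert abs(np.mean(sizes) - mean) < 4 * sigma

    def test_partition_covers_grid_disjointly(self):
        rng = np.random.default_rng(1)
        img = Image(ImageGrid(16, 16), (rng.random((16, 16)) > 0.6).astype(float))
        part = make_partition(img, 0.3, rng)
        assert np.all(part.non_fixed ^ part.fixed)
        assert np.all(part.non_fixed | ~part.boundary)  # boundary subset of U


class TestSmooth:
    def test_blend_zero_is_identity(self):
        img = Image(ImageGrid(8, 8), np.random.default_rng(0).random((8, 8)))
        assert np.array_equal(smooth(img, 0.0).values, img.values)

    @pytest.mark.parametrize("b", [0.1, 0.5, 1.0])
    def test_constant_image_unchanged(self, b):
        img = Image.full(ImageGrid(8, 8), 2.5)
        np.testing.assert_allclose(smooth(img, b).values, 2.5)

    def test_single_pixel_hand_computation(self):
        vals = np.zeros((7, 7))
        vals[3, 3] = 1.0
        out = smooth(Image(ImageGrid(7, 7), vals), 0.5).values
        assert out[3, 3] == pytest.approx(0.5)
        assert out[2, 2] == pytest.approx(0.5 / 8)
        assert out[3, 4] == pytest.approx(0.5 / 8)
        assert out[1, 1] == pytest.approx(0.0)

    def test_border_uses_ingrid_neighbours_only(self):
        vals = np.zeros((5, 5))
        vals[0, 1] = 1.0
        out = smooth(Image(ImageGrid(5, 5), vals), 1.0).values
        # corner (0,0) has 3 in-grid neighbours, one of which is the unit pixel
        assert out[0, 0] == pytest.approx(1.0 / 3)


class TestTermination:
    def _trace(self, dists=None, fracs=None):
        trace = ReconstructionTrace()
        n = len(dists or fracs)
        for i in range(n):
            trace.append(TraceRecord(
                iteration=i + 1, level=0, time_s=0.0,
                proj_distance=dists[i] if dists else 1.0,
                modified_pixels=0,
                modified_fraction=fracs[i] if fracs else 0.0,
                work_units=0.0,
            ))
        return trace

    def test_max_iterations(self):
        spec = TerminationSpec("max_iterations", 10, 1)
        assert check_termination(self._trace(dists=[1.0] * 10), spec)
        assert not check_termination(self._trace(dists=[1.0] * 9), spec)

    def test_distance_delta_streak(self):
        spec = TerminationSpec("projection_distance_delta", 1e-3, 3, relative=False)
        held = self._trace(dists=[5.0, 1.0, 1.0001, 1.0002, 1.0001])
        assert check_termination(held, spec)
        broken = self._trace(dists=[1.0, 1.0001, 6.0, 6.0001, 6.0])
        assert not check_termination(broken, spec)

    def test_modified_pixels_patience(self):
        spec = TerminationSpec("modified_pixels", 0.01, 2)
        assert check_termination(self._trace(fracs=[0.5, 0.005, 0.004]), spec)
        assert not check_termination(self._trace(fracs=[0.005, 0.5]), spec)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            TerminationSpec("banana", 1.0, 1)


class TestDARTLoop:
    def test_recovers_disk_with_holes(self, dart_problem_64, binary_model):
        phantom, grid, sino = dart_problem_64
        cfg = DARTConfig(rng_seed=0, termination=TerminationSpec("max_iterations", 50, 1))
        _, seg, trace = dart_reconstruct(sino, grid, binary_model, cfg, ground_truth=phantom)
        assert trace.records[-1].rnmp < 0.01
        assert rnmp(phantom, seg, binary_model) < 0.01

    def test_deterministic_given_seed(self, dart_problem_64, binary_model):
        phantom, grid, sino = dart_problem_64
        cfg = DARTConfig(rng_seed=42, termination=TerminationSpec("max_iterations", 8, 1))
        out1 = dart_reconstruct(sino, grid, binary_model, cfg)
        out2 = dart_reconstruct(sino, grid, binary_model, cfg)
        assert np.array_equal(out1[0].values, out2[0].values)
        assert np.array_equal(out1[1].values, out2[1].values)

    def test_exact_recovery_with_many_projections(self, binary_model):
        from mdart import default_geometry, disk_with_holes, forward_project

        grid = ImageGrid(32, 32, 1.0)
        phantom = disk_with_holes(32, disk_radius=12, hole_radius=3, n_holes=2, seed=3)
        sino = forward_project(phantom, default_geometry(grid, 30, "parallel"))
        cfg = DARTConfig(rng_seed=0, termination=TerminationSpec("max_iterations", 30, 1))
        _, seg, _ = dart_reconstruct(sino, grid, binary_model, cfg)
        assert rnmp(phantom, seg, binary_model) == 0.0

    def test_interior_conserved_without_randomness_or_smoothing(self, binary_model):
        """With p=0 and no smoothing the deep interior stays pinned.

        The boundary can creep by at most one pixel per DART iteration, so
        pixels farther from the initial boundary than the iteration count
        keep their first segmentation.
        """
        from scipy.ndimage import binary_dilation

        from mdart import default_geometry, disk_with_holes, forward_project, sirt_run

        grid = ImageGrid(32, 32, 1.0)
        phantom = disk_with_holes(32, disk_radius=12, hole_radius=3, n_holes=1, seed=1)
        sino = forward_project(phantom, default_geometry(grid, 20, "parallel"))
        n_dart_iters = 5
        cfg = DARTConfig(
            rng_seed=0, fix_probability=0.0, smoothing_blend=0.0,
            initial_arm_iters=100,
            termination=TerminationSpec("max_iterations", n_dart_iters, 1),
        )
        initial = sirt_run(Image.zeros(grid), sino, 100)
        seg0 = segment(initial, binary_model)
        near_boundary = binary_dilation(
            boundary_pixels(seg0), iterations=n_dart_iters + 1
        )
        cont, _, _ = dart_reconstruct(sino, grid, binary_model, cfg)
        protected = ~near_boundary
        np.testing.assert_array_equal(
            segment(cont, binary_model).values[protected], seg0.values[protected]
        )

    def test_budget_zero_work_skips_loop(self, dart_problem_64, binary_model):
        phantom, grid, sino = dart_problem_64
        cfg = DARTConfig(rng_seed=0, initial_arm_iters=50)
        _, _, trace = dart_reconstruct(
            sino, grid, binary_model, cfg, budget=Budget(max_work=50)
        )
        assert len(trace) == 0  # initial reconstruction exhausted the budget

    def test_fixed_interior_values_are_grey_levels_in_trace(self, dart_problem_64, binary_model):
        phantom, grid, sino = dart_problem_64
        cfg = DARTConfig(rng_seed=0, fix_probability=0.0, smoothing_blend=0.0,
                         termination=TerminationSpec("max_iterations", 3, 1))
        cont, _, _ = dart_reconstruct(sino, grid, binary_model, cfg)
        seg = segment(cont, binary_model)
        interior = ~boundary_pixels(seg)
        # far-from-boundary pixels were frozen at material values all along
        vals = cont.values[interior]
        dist_to_levels = np.minimum(np.abs(vals - 0.0), np.abs(vals - 1.0))
        assert np.quantile(dist_to_levels, 0.95) < 1e-6
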