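"""DBSCAN-derived grids and dwell-time binning."""

from __future__ import annotations

import numpy as np
import pytest

from scanpathkit import (
    bin_dwell,
    derive_core_radius,
    fit_dbscan,
    group_dwell_diff,
    make_grid,
)

from _oracles import containment_cell, dbscan_bruteforce, same_partition


class TestFitDbscan:
    def test_two_separated_blobs(self, rng):
        blob_a = rng.normal((100, 100), 3, size=(10, 2))
        blob_b = rng.normal((600, 100), 3, size=(10, 2))
        out = fit_dbscan(np.vstack([blob_a, blob_b]), eps=20, min_pts=4)
        assert out.n_clusters == 2
        assert out.n_noise == 0

    def test_all_isolated_points_are_noise(self):
        pts = [(0, 0), (100, 0), (0, 100), (100, 100)]
        out = fit_dbscan(pts, eps=10, min_pts=2)
        assert out.n_clusters == 0 and out.n_noise == 4

    def test_single_point_min_pts_one(self):
        out = fit_dbscan([(5.0, 5.0)], eps=1, min_pts=1)
        assert out.n_clusters == 1 and bool(out.core[0])

    def test_empty_input(self):
        out = fit_dbscan([], eps=1, min_pts=1)
        assert len(out.labels) == 0

    @pytest.mark.parametrize("geometry", ["blobs", "ring", "uniform"])
    def test_matches_bruteforce_reference(self, geometry, rng):
        for _ in range(5):
            if geometry == "blobs":
                centers = rng.uniform(0, 1000, size=(4, 2))
                pts = np.vstack([rng.normal(c, 15, size=(50, 2)) for c in centers])
            elif geometry == "ring":
                theta = rng.uniform(0, 2 * np.pi, 200)
                r = rng.normal(200, 8, 200)
                pts = np.column_stack([500 + r * np.cos(theta), 500 + r * np.sin(theta)])
            else:
                pts = rng.uniform(0, 1000, size=(200, 2))
            out = fit_dbscan(pts, eps=30, min_pts=5)
            ref_labels, ref_core = dbscan_bruteforce(pts, eps=30, min_pts=5)
            np.testing.assert_array_equal(out.core, ref_core)
            assert same_partition(out.labels, ref_labels)


class TestDeriveCoreRadius:
    def test_coincident_points_core_at_smallest_radius(self):
        pts = [(50.0, 50.0)] * 5
        assert derive_core_radius(pts, 5, (32, 16, 8, 4, 2, 1)) == 1.0

    def test_square_corner_points(self):
        pts = [(0, 0), (10, 0), (0, 10), (10, 10)]
        # diagonal ~14.14: all four neighbours only within eps >= 14.14
        assert derive_core_radius(pts, 4, (32, 16, 8)) == 16.0
        # brute check: at eps=8 no point has 4 neighbours
        d = np.linalg.norm(
            np.array(pts)[:, None] - np.array(pts)[None, :], axis=2
        )
        assert ((d <= 8).sum(axis=1) < 4).all()
        assert ((d <= 16).sum(axis=1) >= 4).any()

    def test_no_core_returns_largest_with_warning(self):
        pts = [(0, 0), (500, 500)]
        with pytest.warns(UserWarning, match="no candidate"):
            assert derive_core_radius(pts, 2, (32, 16)) == 32.0

    def test_monotone_in_min_pts(self, rng):
        pts = rng.uniform(0, 500, size=(80, 2))
        ladder = (64, 48, 32, 24, 16, 12, 8)
        radii = [derive_core_radius(pts, m, ladder) for m in (2, 4, 8, 16)]
        assert radii == sorted(radii)

    def test_empty_points_error(self):
        with pytest.raises(ValueError):
            derive_core_radius([], 3)


class TestMakeGrid:
    def test_exactly_divisible(self):
        g = make_grid(1000, 500, 50)
        assert (g.n_cols, g.n_rows) == (10, 5)
        assert (g.cell_width, g.cell_height) == (100.0, 100.0)
        assert g.base_dimension == 100.0

    def test_rectangular_stretch(self):
        g = make_grid(1050, 500, 50)
        assert g.n_cols == 10 and g.cell_width == 105.0
        assert g.cell_width >= g.base_dimension and g.cell_height >= g.base_dimension

    def test_oversized_base_gives_single_cell(self):
        with pytest.warns(UserWarning, match="single-cell"):
            g = make_grid(1000, 500, 600)
        assert (g.n_cols, g.n_rows) == (1, 1)

    def test_tiles_stimulus_exactly(self):
        for w, h, r in [(1280, 960, 32), (1050, 500, 24), (640, 480, 8)]:
            g = make_grid(w, h, r)
            assert g.n_cols * g.cell_width == pytest.approx(w)
            assert g.n_rows * g.cell_height == pytest.approx(h)


class TestBinDwell:
    def test_single_fixation_at_cell_center(self, fixation_factory):
        g = make_grid(1000, 500, 50)
        f = fixation_factory(x=150.0, y=150.0, duration=300.0)
        dwell = bin_dwell([f], g)
        assert dwell.values[1, 1] == 300.0
        assert dwell.values.sum() == 300.0

    def test_dwell_conservation(self, rng, fixation_factory):
        g = make_grid(1280, 960, 32)
        fixations = [
            fixation_factory(onset=i * 200.0, x=rng.uniform(-100, 1400),
                             y=rng.uniform(-100, 1100), duration=rng.uniform(50, 600))
            for i in range(1000)
        ]
        dwell = bin_dwell(fixations, g)
        total = sum(f.duration for f in fixations)
        assert dwell.values.sum() + dwell.excluded_duration == pytest.approx(total)

    def test_boundary_point_goes_to_higher_index_cell(self, fixation_factory):
        g = make_grid(1000, 500, 50)
        f = fixation_factory(x=100.0, y=200.0)  # exactly on interior boundaries
        dwell = bin_dwell([f], g)
        assert dwell.values[2, 1] == f.duration
        assert containment_cell(100.0, 200.0, g) == (2, 1)

    def test_cell_assignment_matches_containment_scan(self, rng):
        g = make_grid(1050, 500, 24)
        for _ in range(500):
            x, y = rng.uniform(-20, 1070), rng.uniform(-20, 520)
            assert g.cell_of(x, y) == containment_cell(x, y, g)

    def test_stimulus_edge_belongs_to_last_cell(self):
        g = make_grid(1000, 500, 50)
        assert g.cell_of(1000.0, 500.0) == (g.n_rows - 1, g.n_cols - 1)


class TestGroupDwellDiff:
    def test_identical_grids_zero_diff(self, rng, fixation_factory):
        g = make_grid(1000, 500, 50)
        fx = [fixation_factory(onset=i * 200.0, x=rng.uniform(0, 1000),
                               y=rng.uniform(0, 500)) for i in range(50)]
        a = bin_dwell(fx, g)
        diff = group_dwell_diff(a, a)
        np.testing.assert_array_equal(diff.diff, 0.0)
        assert diff.argmax_a == diff.argmax_b

    def test_diff_against_empty_grid_is_identity(self, fixation_factory):
        g = make_grid(1000, 500, 50)
        a = bin_dwell([fixation_factory(x=555, y=255, duration=420.0)], g)
        b = bin_dwell([], g)
        diff = group_dwell_diff(a, b)
        np.testing.assert_array_equal(diff.diff, a.values)

    def test_mismatched_gridspec_error(self, fixation_factory):
        a = bin_dwell([], make_grid(1000, 500, 50))
        b = bin_dwell([], make_grid(1000, 500, 25))
        with pytest.raises(ValueError, match="GridSpec"):
            group_dwell_diff(a, b)

    def test_group_hotspots_detected_on_synthetic_data(
        self, correct_model, ecg_layout
    ):
        """Groups biased toward different AOIs produce different argmax cells."""
        from scanpathkit import bias_toward_aoi, simulate_study

        model_a = bias_toward_aoi(correct_model, "E", 0.6)
        model_b = bias_toward_aoi(correct_model, "L", 0.6)
        fixations, groups = simulate_study(model_a, model_b, 10, 10, seed=7)
        grid = make_grid(ecg_layout.width, ecg_layout.height, 48)
        by_group = {
            g: [f for f in fixations
                if groups.group_of(f.participant_id, f.stimulus_id) == g]
            for g in ("correct", "incorrect")
        }
        dwell_a = bin_dwell(by_group["correct"], grid)
        dwell_b = bin_dwell(by_group["incorrect"], grid)
        assert dwell_a.argmax_cell != dwell_b.argmax_cell
        # the hot cells fall inside the biased AOIs
        ra, ca = dwell_a.argmax_cell
        e = next(a for a in ecg_layout if a.label == "E")
        assert e.contains((ca + 0.5) * grid.cell_width, (ra + 0.5) * grid.cell_height)
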