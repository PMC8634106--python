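"""Core 3D-QAM computation: surfaces, signed fields, margins, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qam3d import (
    EmptyMaskError,
    IncompatibleGridsError,
    LabelMask,
    VoxelGrid,
    apply_subcapsular_exclusion,
    compute_margin_distribution,
    export_margin_surface,
    extract_surface_voxels,
    signed_distance_field,
    summarize_margins,
)
from qam3d.margins import MarginDistribution
from qam3d.phantom import make_phantom_case, rasterize_ellipsoid, sphere_pair_grid


def _single_voxel_mask(spacing=(1.0, 1.0, 1.0)):
    grid = VoxelGrid((7, 7, 7), spacing)
    occ = np.zeros((7, 7, 7), dtype=bool)
    occ[3, 3, 3] = True
    return LabelMask(grid, occ, "single")


class TestSurfaceExtraction:
    def test_single_voxel_is_its_own_surface(self):
        surf = extract_surface_voxels(_single_voxel_mask())
        assert surf.n_total == 1
        assert tuple(surf.voxel_indices[0]) == (3, 3, 3)

    def test_cube_surface_excludes_interior(self, cube_mask):
        # 4^3 cube: all but the 2^3 interior are boundary voxels
        assert extract_surface_voxels(cube_mask).n_total == 64 - 8

    def test_full_grid_boundary_treated_as_surface(self):
        grid = VoxelGrid((4, 4, 4), (1, 1, 1))
        mask = LabelMask(grid, np.ones((4, 4, 4)), "full")
        assert extract_surface_voxels(mask).n_total == 64 - 8

    def test_solid_3cube_has_26_surface_voxels(self):
        grid = VoxelGrid((5, 5, 5), (1, 1, 1))
        occ = np.zeros((5, 5, 5), dtype=bool)
        occ[1:4, 1:4, 1:4] = True
        assert extract_surface_voxels(LabelMask(grid, occ, "c3")).n_total == 26

    def test_empty_mask_raises(self):
        grid = VoxelGrid((4, 4, 4), (1, 1, 1))
        with pytest.raises(EmptyMaskError):
            extract_surface_voxels(LabelMask(grid, np.zeros((4, 4, 4)), "e"))


class TestSignedDistanceField:
    def test_single_voxel_isotropic(self):
        sdf = signed_distance_field(_single_voxel_mask()).signed_mm
        assert sdf[3, 3, 3] == pytest.approx(1.0)
        assert sdf[4, 3, 3] == pytest.approx(-1.0)
        assert sdf[4, 4, 4] == pytest.approx(-np.sqrt(3.0))

    def test_single_voxel_anisotropic(self):
        sdf = signed_distance_field(_single_voxel_mask((1.0, 1.0, 2.0))).signed_mm
        assert sdf[3, 3, 4] == pytest.approx(-2.0)
        assert sdf[4, 3, 3] == pytest.approx(-1.0)

    def test_sphere_center_value_close_to_radius(self):
        case = make_phantom_case(sphere_pair_grid(10, 15, 0, 0.5))
        sdf = signed_distance_field(case.tumor)
        center_idx = np.array(np.unravel_index(np.argmax(sdf.signed_mm), sdf.signed_mm.shape))
        assert sdf.signed_mm[tuple(center_idx)] == pytest.approx(10.0, abs=0.87)

    def test_positive_exactly_on_occupied(self, cube_mask):
        sdf = signed_distance_field(cube_mask).signed_mm
        assert np.all(sdf[cube_mask.occupancy] > 0)
        assert np.all(sdf[~cube_mask.occupancy] < 0)
        assert np.abs(sdf).max() <= cube_mask.grid.diagonal_mm


class TestMarginDistribution:
    def test_identity_masks_zero_margin(self, cube_mask):
        # coincident tumor and ablation boundaries: margin is zero everywhere
        dist = compute_margin_distribution(cube_mask, cube_mask)
        assert np.abs(dist.margins_mm).max() < 0.3

    def test_identity_masks_voxel_convention(self, cube_mask):
        # coarse convention: each surface voxel's nearest background is a face neighbor
        dist = compute_margin_distribution(cube_mask, cube_mask, refine=False)
        assert np.allclose(dist.margins_mm, 1.0)

    def test_concentric_margins_near_five(self, concentric_case_s1):
        dist = compute_margin_distribution(
            concentric_case_s1.tumor, concentric_case_s1.ablation
        )
        diag = concentric_case_s1.tumor.grid.voxel_diagonal_mm
        assert np.all(np.abs(dist.margins_mm - 5.0) <= diag)
        assert summarize_margins(dist).pct_below[0.0] == 0.0

    def test_offset7_residual_fraction_matches_cap_oracle(self, offset7_case_s05):
        dist = compute_margin_distribution(offset7_case_s05.tumor, offset7_case_s05.ablation)
        s = summarize_margins(dist)
        assert s.pct_below[0.0] == pytest.approx(22.857, abs=2.0)

    def test_role_swap_negates_concentric_margins(self, concentric_case_s1):
        fwd = compute_margin_distribution(concentric_case_s1.tumor, concentric_case_s1.ablation)
        rev = compute_margin_distribution(concentric_case_s1.ablation, concentric_case_s1.tumor)
        diag = concentric_case_s1.tumor.grid.voxel_diagonal_mm
        assert np.all(np.abs(fwd.margins_mm - 5.0) <= diag)
        assert np.all(np.abs(rev.margins_mm + 5.0) <= diag)

    def test_translation_invariance_whole_voxel(self):
        # generous padding keeps the smoothing kernel clear of the grid edge
        case = make_phantom_case(sphere_pair_grid(10.0, 15.0, 0.0, 1.0, pad_mm=9.0))
        t, a = case.tumor, case.ablation
        shift = (2, 3, 1)
        t2 = LabelMask(t.grid, np.roll(t.occupancy, shift, axis=(0, 1, 2)), "t2")
        a2 = LabelMask(a.grid, np.roll(a.occupancy, shift, axis=(0, 1, 2)), "a2")
        s1 = summarize_margins(compute_margin_distribution(t, a))
        s2 = summarize_margins(compute_margin_distribution(t2, a2))
        # identical up to float noise of absolute mesh coordinates
        assert s1.mam_mm == pytest.approx(s2.mam_mm, abs=1e-5)
        assert s1.median_mm == pytest.approx(s2.median_mm, abs=1e-5)
        for k in s1.pct_below:
            assert s1.pct_below[k] == pytest.approx(s2.pct_below[k], abs=1e-5)

    def test_incompatible_grids_refused(self, cube_mask):
        other_grid = VoxelGrid((10, 10, 10), (1.0, 1.0, 1.1))
        other = LabelMask(other_grid, cube_mask.occupancy.copy(), "a")
        with pytest.raises(IncompatibleGridsError):
            compute_margin_distribution(cube_mask, other)

    def test_empty_tumor_or_ablation_rejected(self, cube_mask):
        empty = LabelMask(cube_mask.grid, np.zeros((10, 10, 10)), "e")
        with pytest.raises(EmptyMaskError):
            compute_margin_distribution(empty, cube_mask)
        with pytest.raises(EmptyMaskError):
            compute_margin_distribution(cube_mask, empty)


class TestSubcapsularExclusion:
    def test_full_grid_liver_excludes_nothing(self, concentric_case_s1):
        t = concentric_case_s1.tumor
        liver = LabelMask(t.grid, np.ones(t.grid.shape), "liver")
        surf = extract_surface_voxels(t)
        out = apply_subcapsular_exclusion(surf, liver, band_mm=0.0)
        assert out.n_included == out.n_total

    def test_halfspace_liver_excludes_half(self, halfspace_liver_case):
        case = halfspace_liver_case
        surf = extract_surface_voxels(case.tumor)
        out = apply_subcapsular_exclusion(surf, case.liver, band_mm=0.0)
        frac = 1.0 - out.n_included / out.n_total
        assert frac == pytest.approx(0.5, abs=0.05)
        assert all(
            r == "subcapsular" for r in out.exclusion_reason[~out.included]
        )

    def test_exclusion_never_changes_retained_margins(self, halfspace_liver_case):
        case = halfspace_liver_case
        with_liver = compute_margin_distribution(
            case.tumor, case.ablation, liver=case.liver, band_mm=0.0
        )
        without = compute_margin_distribution(case.tumor, case.ablation)
        verts, _, all_margins, included = with_liver.mesh
        # margins of retained elements identical to the unfiltered computation
        assert np.array_equal(all_margins[included], with_liver.margins_mm)
        assert np.array_equal(without.mesh[2], all_margins)

    def test_tumor_outside_liver_raises(self, concentric_case_s1):
        t = concentric_case_s1.tumor
        liver = LabelMask(t.grid, np.zeros(t.grid.shape), "liver")
        liver.occupancy[0, 0, 0] = True  # non-empty but disjoint from tumor
        with pytest.raises(EmptyMaskError, match="no assessable"):
            compute_margin_distribution(t, concentric_case_s1.ablation, liver=liver)

    def test_band_widens_exclusion(self, halfspace_liver_case):
        case = halfspace_liver_case
        d0 = compute_margin_distribution(case.tumor, case.ablation, liver=case.liver, band_mm=0.0)
        d3 = compute_margin_distribution(case.tumor, case.ablation, liver=case.liver, band_mm=3.0)
        assert d3.n_excluded_subcapsular > d0.n_excluded_subcapsular


class TestSummaries:
    def _dist(self, margins):
        m = np.asarray(margins, dtype=float)
        return MarginDistribution(m, len(m), 0)

    def test_hand_counted_example(self):
        s = summarize_margins(self._dist([-2, 1, 3, 6, 6]), thresholds_mm=[0, 1, 5])
        assert s.mam_mm == -2 and s.median_mm == 3 and s.max_mm == 6
        assert s.pct_below[0.0] == 20 and s.pct_below[1.0] == 20 and s.pct_below[5.0] == 60

    def test_strict_threshold_and_categories_at_exact_five(self):
        s = summarize_margins(self._dist([5.0] * 4), thresholds_mm=[5])
        assert s.pct_below[5.0] == 0.0  # strict <
        assert s.category_pct == {"red": 0.0, "yellow": 100.0, "green": 0.0}

    def test_category_percentages_sum_to_100(self):
        rng = np.random.default_rng(3)
        s = summarize_margins(self._dist(rng.normal(2, 4, size=500)))
        assert sum(s.category_pct.values()) == pytest.approx(100.0, abs=1e-9)
        assert s.mam_mm <= s.median_mm <= s.max_mm

    def test_pct_below_nondecreasing(self):
        rng = np.random.default_rng(4)
        s = summarize_margins(self._dist(rng.normal(0, 3, size=300)))
        vals = [s.pct_below[float(t)] for t in range(11)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_histogram_bins_left_closed_integer_edges(self):
        s = summarize_margins(self._dist([-0.5, 0.0, 0.9, 1.0, 4.99, 5.0, 6.2]))
        bins = {(b["bin_left_mm"], b["bin_right_mm"]): b for b in s.histogram}
        assert bins[(-1.0, 0.0)]["count"] == 1 and bins[(-1.0, 0.0)]["category"] == "red"
        assert bins[(0.0, 1.0)]["count"] == 2  # 0.0 and 0.9; 1.0 goes right
        assert bins[(1.0, 2.0)]["count"] == 1
        assert bins[(5.0, 6.0)]["category"] == "green"
        assert sum(b["count"] for b in s.histogram) == 7

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            MarginDistribution(np.array([]), 5, 2)

    @given(
        st.lists(
            st.floats(min_value=-30, max_value=30, allow_nan=False), min_size=1, max_size=60
        )
    )
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_summary_invariants_hold_for_any_distribution(self, margins):
        s = summarize_margins(self._dist(margins))
        assert s.mam_mm <= s.median_mm <= s.max_mm
        assert sum(s.category_pct.values()) == pytest.approx(100.0, abs=1e-9)
        vals = [s.pct_below[float(t)] for t in range(11)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        assert sum(b["count"] for b in s.histogram) == len(margins)
        assert sum(b["percent"] for b in s.histogram) == pytest.approx(100.0, abs=1e-9)


class TestSurfaceExport:
    def test_mesh_written_finite_and_in_oracle_range(self, tmp_path, concentric_case_s1):
        case = concentric_case_s1
        dist = compute_margin_distribution(case.tumor, case.ablation)
        path = export_margin_surface(case.tumor, dist, tmp_path / "m.ply")
        text = path.read_text().splitlines()
        n_verts = int(next(l for l in text if l.startswith("element vertex")).split()[-1])
        assert n_verts > 0
        header_end = text.index("end_header")
        diag = case.tumor.grid.voxel_diagonal_mm
        scalars = [float(l.split()[3]) for l in text[header_end + 1 : header_end + 1 + n_verts]]
        assert all(np.isfinite(scalars))
        assert min(scalars) >= case.oracle.min_margin_mm - diag
        assert max(scalars) <= case.oracle.max_margin_mm + diag

    def test_reexport_is_byte_identical(self, tmp_path, concentric_case_s1):
        case = concentric_case_s1
        dist = compute_margin_distribution(case.tumor, case.ablation)
        p1 = export_margin_surface(case.tumor, dist, tmp_path / "a.ply")
        p2 = export_margin_surface(case.tumor, dist, tmp_path / "b.ply")
        assert p1.read_bytes() == p2.read_bytes()

    def test_voxel_convention_export(self, tmp_path, cube_mask):
        dist = compute_margin_distribution(cube_mask, cube_mask, refine=False)
        path = export_margin_surface(cube_mask, dist, tmp_path / "c.ply")
        assert path.read_text().startswith("ply")
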