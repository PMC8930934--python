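"""Morphometry: per-slice primitives, aggregates, and oracle equivalence."""

import numpy as np
import pytest

import meniquant as mq
from meniquant.morphometry import restrict_to_slices

from _oracles import OracleUndefined, oracle_footprint, oracle_measures, random_compartment
from conftest import make_simple_seg


def seg_from_masks(men, plat, spacing=(1.0, 1.0, 1.0)):
    return mq.SegmentedCompartment(men, plat, spacing=spacing)


class TestFootprint:
    def test_single_voxel_identity(self):
        men = np.zeros((5, 4, 8), dtype=bool)
        men[3, 2, 5] = True
        plat = np.ones((5, 8), dtype=bool)
        fp = mq.meniscus_tibial_footprint(seg_from_masks(men, plat))
        assert fp[3, 5]
        assert fp.sum() == 1

    def test_projection_collapses_z(self):
        men = np.zeros((4, 6, 6), dtype=bool)
        men[2, 1:5, 4] = True  # four voxels in one column
        plat = np.ones((4, 6), dtype=bool)
        fp = mq.meniscus_tibial_footprint(seg_from_masks(men, plat))
        assert fp.sum() == 1 and fp[2, 4]

    def test_matches_per_column_scan(self, rng):
        men = rng.random((8, 8, 8)) < 0.3
        men[0, 0, 0] = True
        plat = np.ones((8, 8), dtype=bool)
        fp = mq.meniscus_tibial_footprint(seg_from_masks(men, plat))
        assert fp.tolist() == oracle_footprint(men)

    def test_empty_meniscus_raises(self):
        men = np.zeros((3, 3, 3), dtype=bool)
        plat = np.ones((3, 3), dtype=bool)
        with pytest.raises(mq.EmptyStructureError):
            mq.meniscus_tibial_footprint(seg_from_masks(men, plat))


class TestSliceExtrusion:
    def test_protruding_meniscus_positive(self, simple_seg):
        # plateau x in [0, 9], meniscus x in [7, 12], 1 mm spacing
        assert mq.extrusion_distance_slice(simple_seg, 0) == pytest.approx(3.0)

    def test_coincident_margins_zero(self):
        seg = make_simple_seg(plateau_x_hi=9, meniscus_x=(5, 9))
        assert mq.extrusion_distance_slice(seg, 1) == pytest.approx(0.0)

    def test_internal_margin_negative(self):
        seg = make_simple_seg(plateau_x_hi=9, meniscus_x=(2, 7),
                              spacing=(1.5, 0.37, 0.37))
        assert mq.extrusion_distance_slice(seg, 0) == pytest.approx(-0.74)

    def test_slice_without_plateau_raises(self):
        seg = make_simple_seg()
        seg.plateau_footprint[1, :] = False
        with pytest.raises(mq.UndefinedSliceError):
            mq.extrusion_distance_slice(seg, 1)


class TestCentralWindow:
    @pytest.mark.parametrize(
        "occupied, n, expected",
        [
            (range(10, 21), 1, [15]),   # odd count midpoint
            (range(10, 22), 1, [15]),   # even count: anterior middle slice
            (range(10, 21), 5, [13, 14, 15, 16, 17]),
            (range(10, 12), 5, [10, 11]),  # window clipped to occupied slices
        ],
    )
    def test_window_indices(self, occupied, n, expected):
        ny = max(occupied) + 3
        men = np.zeros((ny, 2, 4), dtype=bool)
        for y in occupied:
            men[y, 0, 1] = True
        plat = np.ones((ny, 4), dtype=bool)
        assert mq.central_window(seg_from_masks(men, plat), n) == expected

    def test_empty_meniscus_raises(self):
        men = np.zeros((4, 2, 4), dtype=bool)
        plat = np.ones((4, 4), dtype=bool)
        with pytest.raises(mq.EmptyStructureError):
            mq.central_window(seg_from_masks(men, plat), 1)


class TestAggregateExtrusion:
    def make_offsets_seg(self, offsets, spacing=(1.0, 1.0, 1.0)):
        seg, _ = mq.make_box_phantom(
            mq.BoxPhantomSpec(n_slices=len(offsets), plateau_extent_x=10,
                              meniscus_extent_x=4, external_offset=offsets,
                              meniscus_height=2, spacing=spacing)
        )
        return seg

    def test_mean_is_arithmetic_mean(self):
        seg = self.make_offsets_seg([2, 3, 4])
        assert mq.mean_extrusion(seg, "all") == pytest.approx(3.0)

    def test_signed_mean_symmetry(self):
        seg = self.make_offsets_seg([-1, 0, 1])
        assert mq.mean_extrusion(seg, "all") == pytest.approx(0.0)

    def test_max_of_slices(self):
        seg = self.make_offsets_seg([2, 3, 4])
        assert mq.max_extrusion(seg) == pytest.approx(4.0)

    def test_max_of_constant_negative(self):
        seg = self.make_offsets_seg([-1, -1, -1], spacing=(1.0, 1.0, 0.5))
        assert mq.max_extrusion(seg) == pytest.approx(-0.5)

    def test_linear_offsets_match_brute_force(self):
        offsets = list(range(-2, 9))  # 11 slices, linearly varying margins
        seg = self.make_offsets_seg(offsets)
        expected = oracle_measures(seg.meniscus_mask, seg.plateau_footprint,
                                   seg.spacing)
        assert mq.mean_extrusion(seg, "all") == pytest.approx(
            expected["mean_extrusion_mm"], rel=1e-12)
        assert mq.max_extrusion(seg) == pytest.approx(
            expected["max_extrusion_mm"], rel=1e-12)

    def test_undefined_slices_excluded_not_zero_filled(self):
        seg = self.make_offsets_seg([2, 4])
        seg.plateau_footprint[0, :] = False  # slice 0 now ineligible
        assert mq.mean_extrusion(seg, "all") == pytest.approx(4.0)

    def test_no_eligible_slice_raises(self):
        seg = self.make_offsets_seg([2, 4])
        seg.plateau_footprint[:, :] = False
        with pytest.raises(mq.MorphometryError):
            mq.mean_extrusion(seg, "all")


class TestAreaMeasures:
    def test_full_cover_and_zero_extrusion_area(self):
        seg = make_simple_seg(plateau_x_hi=9, meniscus_x=(0, 9))
        assert mq.coverage_pct(seg) == pytest.approx(100.0)
        assert mq.extrusion_area_pct(seg) == pytest.approx(0.0)

    def test_disjoint_footprints(self):
        seg = make_simple_seg(plateau_x_hi=4, meniscus_x=(6, 9))
        assert mq.coverage_pct(seg) == pytest.approx(0.0)
        assert mq.extrusion_area_pct(seg) == pytest.approx(100.0)

    def test_coverage_cell_counting(self):
        # plateau 100 cells (10 slices x 10), 37 of them covered
        men = np.zeros((10, 2, 16), dtype=bool)
        plat = np.zeros((10, 16), dtype=bool)
        plat[:, :10] = True
        men[:9, 0, 6:10] = True  # 4 covered cells in 9 slices
        men[9, 0, 9] = True      # 1 covered cell in the last
        seg = seg_from_masks(men, plat)
        assert mq.coverage_pct(seg) == pytest.approx(37.0)

    def test_extrusion_area_cell_counting(self):
        # meniscus footprint 50 cells, 10 of them external to the plateau
        men = np.zeros((10, 2, 16), dtype=bool)
        plat = np.zeros((10, 16), dtype=bool)
        plat[:, :10] = True
        men[:, 0, 6:11] = True  # 5 cells/slice, 1 outside the plateau
        seg = seg_from_masks(men, plat)
        assert int(mq.meniscus_tibial_footprint(seg).sum()) == 50
        assert mq.extrusion_area_pct(seg) == pytest.approx(20.0)


class TestMorphologyMeasures:
    def test_uniform_slab_heights(self):
        seg = make_simple_seg(height=6, spacing=(1.5, 0.37, 0.37))
        h_mean, h_max = mq.height_stats(seg)
        assert h_mean == pytest.approx(2.22)
        assert h_max == pytest.approx(2.22)

    def test_two_column_heights(self):
        men = np.zeros((1, 5, 4), dtype=bool)
        men[0, :2, 1] = True
        men[0, :4, 2] = True
        plat = np.ones((1, 4), dtype=bool)
        h_mean, h_max = mq.height_stats(seg_from_masks(men, plat, (1.0, 0.5, 1.0)))
        assert h_mean == pytest.approx(1.5)
        assert h_max == pytest.approx(2.0)

    def test_constant_width(self):
        seg = make_simple_seg(meniscus_x=(4, 13), spacing=(1.5, 0.37, 0.37))
        assert mq.width_mean(seg) == pytest.approx(3.7)

    def test_mean_of_two_widths(self):
        men = np.zeros((2, 2, 30), dtype=bool)
        men[0, 0, 0:10] = True
        men[1, 0, 0:20] = True
        plat = np.ones((2, 30), dtype=bool)
        assert mq.width_mean(seg_from_masks(men, plat)) == pytest.approx(15.0)

    def test_volume_unit_and_dess_voxels(self):
        men = np.zeros((10, 10, 10), dtype=bool)
        plat = np.ones((10, 10), dtype=bool)
        assert mq.volume_ml(seg_from_masks(men, plat)) == 0.0
        men.flat[:1000] = True
        seg = seg_from_masks(men, plat, spacing=(1.5, 0.37, 0.37))
        assert mq.volume_ml(seg) == pytest.approx(0.20535)
        seg_unit = seg_from_masks(np.ones((20, 20, 20), dtype=bool),
                                  np.ones((20, 20), dtype=bool))
        assert mq.volume_ml(seg_unit) == pytest.approx(8.0)


class TestComputeAllMeasures:
    def test_random_masks_match_enumeration_oracle(self, rng):
        checked = 0
        for _ in range(40):
            men, plat = random_compartment(rng)
            seg = seg_from_masks(men, plat, spacing=(1.5, 0.37, 0.37))
            try:
                expected = oracle_measures(men, plat, seg.spacing)
            except OracleUndefined:
                with pytest.raises(mq.MorphometryError):
                    mq.compute_all_measures(seg)
                continue
            got = mq.compute_all_measures(seg).as_dict()
            for k, v in expected.items():
                assert got[k] == pytest.approx(v, rel=1e-12, abs=1e-12), k
            checked += 1
        assert checked >= 20

    def test_translation_of_both_masks_is_invariant(self, rng):
        men, plat = random_compartment(rng, max_extent=10)
        seg = seg_from_masks(men, plat)
        pad = 3
        men2 = np.zeros((men.shape[0], men.shape[1], men.shape[2] + pad), dtype=bool)
        plat2 = np.zeros((plat.shape[0], plat.shape[1] + pad), dtype=bool)
        men2[:, :, pad:] = men
        plat2[:, pad:] = plat
        seg2 = seg_from_masks(men2, plat2)
        try:
            m1 = mq.compute_all_measures(seg).as_dict()
        except mq.MorphometryError:
            pytest.skip("degenerate random draw")
        m2 = mq.compute_all_measures(seg2).as_dict()
        for k in m1:
            assert m2[k] == pytest.approx(m1[k], rel=1e-12), k

    def test_external_shift_adds_to_extrusion(self):
        k, dx = 3, 0.37
        seg, _ = mq.make_box_phantom(mq.BoxPhantomSpec(
            n_slices=7, plateau_extent_x=12, meniscus_extent_x=5,
            external_offset=[0, 1, 2, 3, 2, 1, 0], meniscus_height=3,
            spacing=(1.5, 0.37, dx)))
        shifted, _ = mq.make_box_phantom(mq.BoxPhantomSpec(
            n_slices=7, plateau_extent_x=12, meniscus_extent_x=5,
            external_offset=[o + k for o in [0, 1, 2, 3, 2, 1, 0]],
            meniscus_height=3, spacing=(1.5, 0.37, dx)))
        base = mq.compute_all_measures(seg)
        moved = mq.compute_all_measures(shifted)
        for f in ("mean_extrusion_mm", "max_extrusion_mm",
                  "mean_extrusion_central5_mm", "mean_extrusion_central1_mm"):
            assert getattr(moved, f) == pytest.approx(
                getattr(base, f) + k * dx, rel=1e-12)
        assert moved.extrusion_area_pct >= base.extrusion_area_pct

    def test_monotonic_aggregates_and_area_complement(self, rng):
        for _ in range(10):
            men, plat = random_compartment(rng, max_extent=12)
            seg = seg_from_masks(men, plat)
            try:
                m = mq.compute_all_measures(seg)
            except mq.MorphometryError:
                continue
            assert m.max_extrusion_mm >= m.mean_extrusion_mm - 1e-12
            assert m.height_max_mm >= m.height_mean_mm >= 0
            uncovered = 100.0 * (
                (seg.plateau_footprint & ~seg.meniscus_mask.any(axis=1)).sum()
                / seg.plateau_footprint.sum()
            )
            assert m.coverage_pct + uncovered == pytest.approx(100.0)

    def test_windowed_restriction_consistent(self):
        seg, _ = mq.make_box_phantom(mq.BoxPhantomSpec(
            n_slices=9, external_offset=list(range(9))))
        win = mq.central_window(seg, 5)
        sub = restrict_to_slices(seg, win)
        assert mq.mean_extrusion(seg, "central5") == pytest.approx(
            mq.mean_extrusion(sub, "all"), rel=1e-12)
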