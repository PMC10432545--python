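"""Patch extraction and landscape metrics: connectivity semantics,
edge-count perimeters, shape index, size classes and level summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from canopytherm.patch_analysis import (
    SIZE_CLASSES,
    classify_size,
    extract_patches,
    mask_perimeter_m,
    patch_level_summary,
    patch_table,
    shape_index,
)
from canopytherm.raster import LandCover, LandCoverMap


def canopy_map(mask, cell_size=1.0):
    grid = np.where(mask, int(LandCover.TREE_CANOPY), int(LandCover.BARE_LAND))
    return LandCoverMap(grid, cell_size=cell_size)


class TestExtractPatches:
    def test_single_block(self):
        mask = np.zeros((12, 12), dtype=bool)
        mask[1:11, 1:11] = True
        patches = extract_patches(canopy_map(mask))
        assert len(patches) == 1
        assert patches[0].area_m2 == 100.0
        assert patches[0].perimeter_m == 40.0

    def test_diagonal_blocks_connectivity_semantics(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0:2, 0:2] = True
        mask[2:4, 2:4] = True
        assert len(extract_patches(canopy_map(mask), connectivity=4)) == 2
        assert len(extract_patches(canopy_map(mask), connectivity=8)) == 1

    def test_hand_enumerated_component_counts(self):
        # three isolated cells, one of them diagonal to another
        mask = np.zeros((5, 5), dtype=bool)
        mask[[0, 1, 3], [0, 1, 3]] = True
        assert len(extract_patches(canopy_map(mask), connectivity=4)) == 3
        assert len(extract_patches(canopy_map(mask), connectivity=8)) == 2

    def test_empty_class_gives_empty_list(self):
        lc = LandCoverMap(np.full((4, 4), int(LandCover.BARE_LAND)))
        assert extract_patches(lc, LandCover.TREE_CANOPY) == []

    def test_unknown_connectivity_rejected(self):
        with pytest.raises(ValueError, match="connectivity"):
            extract_patches(canopy_map(np.ones((2, 2), bool)), connectivity=6)

    def test_masks_partition_the_class_cells(self):
        rng = np.random.default_rng(2)
        mask = rng.random((30, 30)) < 0.4
        patches = extract_patches(canopy_map(mask))
        union = np.zeros_like(mask)
        for p in patches:
            r0, c0 = p.bbox
            h, w = p.mask.shape
            assert not union[r0:r0 + h, c0:c0 + w][p.mask].any()  # disjoint
            union[r0:r0 + h, c0:c0 + w] |= p.mask
        assert np.array_equal(union, mask)

    def test_area_conservation(self):
        rng = np.random.default_rng(3)
        mask = rng.random((40, 40)) < 0.3
        patches = extract_patches(canopy_map(mask, cell_size=30.0))
        assert sum(p.area_m2 for p in patches) == pytest.approx(
            mask.sum() * 900.0)


class TestPerimeter:
    @pytest.mark.parametrize("cells,expected_m", [
        ([(0, 0)], 4.0),                      # single cell
        ([(0, 0), (1, 0), (1, 1)], 8.0),      # L-shaped triomino
    ])
    def test_hand_counted_edges(self, cells, expected_m):
        mask = np.zeros((3, 3), dtype=bool)
        for r, c in cells:
            mask[r, c] = True
        assert mask_perimeter_m(mask, 1.0) == expected_m

    def test_grid_boundary_counts_as_exposed(self):
        assert mask_perimeter_m(np.ones((10, 10), bool), 1.0) == 40.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mask_perimeter_m(np.zeros((2, 2), bool), 1.0)


class TestShapeIndex:
    def test_luoping_largest_patches(self):
        """Printed area/perimeter of the two largest canopy patches give the
        printed shape indices."""
        assert shape_index(25_170.0, 653_200.0) == pytest.approx(8.79, abs=0.01)
        assert shape_index(32_290.0, 645_400.0) == pytest.approx(11.34, abs=0.01)

    @given(side=st.floats(0.5, 1e4))
    def test_square_closed_form_scale_free(self, side):
        """Any square has A = 2/sqrt(pi), independent of its size."""
        assert shape_index(4 * side, side * side) == pytest.approx(
            2.0 / np.sqrt(np.pi), rel=1e-12)

    @given(e=st.floats(1.0, 1e5), s=st.floats(1.0, 1e8))
    def test_km_hm2_unit_identity(self, e, s):
        """shape_index on metre units equals 5 E_km / sqrt(pi S_hm2)."""
        assert shape_index(e * 1000.0, s * 10_000.0) == pytest.approx(
            5.0 * e / np.sqrt(np.pi * s), rel=1e-12)

    def test_raster_patches_exceed_isoperimetric_floor(self):
        rng = np.random.default_rng(4)
        mask = rng.random((25, 25)) < 0.35
        for p in extract_patches(canopy_map(mask)):
            assert p.shape_index >= 1.0

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            shape_index(0.0, 10.0)
        with pytest.raises(ValueError):
            shape_index(10.0, -1.0)


class TestSizeClasses:
    @pytest.mark.parametrize("area,expected", [
        (0.05, "small"),          # boundary closed below
        (0.051, "medium"),
        (0.12, "medium"),
        (0.20, "medium"),
        (1.00, "large"),
        (5.00, "super_large"),
        (5.01, "extra_large"),
        (65.32, "extra_large"),
    ])
    def test_thresholds(self, area, expected):
        assert classify_size(area) == expected

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            classify_size(0.0)


class TestLevelSummary:
    @staticmethod
    def _patches_of_areas(areas_hm2):
        # geometry-free stand-ins: only area/size class matter here
        from canopytherm.patch_analysis import Patch
        out = []
        for i, a in enumerate(areas_hm2, 1):
            out.append(Patch(id=i, mask=np.ones((1, 1), bool), bbox=(0, 0),
                             cell_size=1.0, area_m2=a * 1e4, perimeter_m=4.0,
                             shape_index=1.13, size_class=classify_size(a)))
        return out

    def test_one_patch_per_level(self):
        summary = patch_level_summary(
            self._patches_of_areas([0.04, 0.10, 0.50, 2.0, 6.0]))
        assert list(summary["count"]) == [1, 1, 1, 1, 1]
        assert summary["pct_of_total_area"].sum() == pytest.approx(100.0)

    def test_luoping_extra_large_share(self):
        """With the published per-level canopy areas, extra-large patches
        hold 59.91% of total patch area."""
        from canopytherm.patch_analysis import Patch
        level_areas = [14.27, 63.89, 122.68, 92.34, 438.19]
        patches = [Patch(id=i, mask=np.ones((1, 1), bool), bbox=(0, 0),
                         cell_size=1.0, area_m2=a * 1e4, perimeter_m=4.0,
                         shape_index=1.13, size_class=cls)
                   for i, (a, cls) in enumerate(zip(level_areas, SIZE_CLASSES))]
        summary = patch_level_summary(patches)
        assert summary.loc["extra_large", "pct_of_total_area"] == \
            pytest.approx(59.91, abs=0.005)
        assert summary["pct_of_total_area"].sum() == pytest.approx(100.0)

    def test_empty_level_reports_zero(self):
        summary = patch_level_summary(self._patches_of_areas([0.04, 6.0]))
        assert summary.loc["medium", "count"] == 0
        assert summary.loc["medium", "pct_of_total_area"] == 0.0

    def test_empty_patch_list_rejected(self):
        with pytest.raises(ValueError):
            patch_level_summary([])


def test_patch_table_ordering_and_columns():
    mask = np.zeros((20, 20), dtype=bool)
    mask[0:3, 0:3] = True
    mask[10:14, 10:18] = True
    table = patch_table(extract_patches(canopy_map(mask, cell_size=30.0)))
    assert list(table["patch_no"]) == [1, 2]
    assert table["area_hm2"].is_monotonic_decreasing
    assert {"area_hm2", "perimeter_km", "shape_index",
            "size_class"} <= set(table.columns)
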