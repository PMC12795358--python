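"""Overlay combination, selection, zonal tabulation and summaries."""

import numpy as np
import pytest
from shapely.geometry import box

from firepriority.grid import GridSpec, Raster
from firepriority.prioritize import (
    COUNT_NODATA,
    CRITERIA_LABELS,
    CriteriaStack,
    PriorityResult,
    RegionSet,
    StackError,
    criteria_count,
    focus_area_km2,
    select,
    summarize,
    zonal_tabulate,
)

CRS = "EPSG:2100"


def stack_from_arrays(grid, a, b, c):
    return CriteriaStack(masks=[
        Raster(grid, np.asarray(arr, dtype=np.uint8), nodata=255, band=lbl)
        for lbl, arr in zip(CRITERIA_LABELS, (a, b, c))
    ])


def random_stack(grid, rng, p=0.4):
    return stack_from_arrays(
        grid, *(rng.random(grid.shape) < p for _ in range(3))
    )


@pytest.fixture
def grid():
    return GridSpec(CRS, 0.0, 2000.0, 100.0, 100.0, 20, 20)


class TestCriteriaCount:
    def test_count_values(self, grid):
        ones = np.ones(grid.shape)
        zeros = np.zeros(grid.shape)
        assert np.all(criteria_count(stack_from_arrays(grid, ones, ones, ones)).values == 3)
        assert np.all(criteria_count(stack_from_arrays(grid, ones, zeros, ones)).values == 2)
        assert np.all(criteria_count(stack_from_arrays(grid, zeros, zeros, zeros)).values == 0)

    def test_nodata_scores_as_not_met_until_all_nodata(self, grid):
        a = np.ones(grid.shape); a[0, 0] = 255
        b = np.ones(grid.shape); b[1, 1] = 255
        c = np.ones(grid.shape)
        count = criteria_count(stack_from_arrays(grid, a, b, c))
        assert count.values[0, 0] == 2
        assert count.values[1, 1] == 2
        a2 = np.full(grid.shape, 255); b2 = a2.copy(); c2 = a2.copy()
        count2 = criteria_count(stack_from_arrays(grid, a2, b2, c2))
        assert np.all(count2.values == COUNT_NODATA)

    def test_permutation_invariance(self, grid):
        rng = np.random.default_rng(11)
        masks = random_stack(grid, rng).masks
        a = criteria_count(CriteriaStack(masks=masks)).values
        b = criteria_count(CriteriaStack(masks=masks[::-1])).values
        np.testing.assert_array_equal(a, b)

    def test_mislabeled_or_unaligned_stack_rejected(self, grid):
        ones = np.ones(grid.shape, dtype=np.uint8)
        with pytest.raises(StackError):
            CriteriaStack(masks=[
                Raster(grid, ones, nodata=255, band="repetitive_fire"),
                Raster(grid, ones, nodata=255, band="repetitive_fire"),
                Raster(grid, ones, nodata=255, band="steep_slope"),
            ])
        other = GridSpec(CRS, 50.0, 2000.0, 100.0, 100.0, 20, 20)
        with pytest.raises(StackError):
            stack_from_arrays(grid, ones, ones, ones).masks  # aligned: fine
            CriteriaStack(masks=[
                Raster(grid, ones, nodata=255, band="repetitive_fire"),
                Raster(grid, ones, nodata=255, band="steep_slope"),
                Raster(other, ones, nodata=255, band="protected_area"),
            ])


class TestSelect:
    def test_two_of_three_is_preliminary_only(self, grid):
        count = Raster(grid, np.full(grid.shape, 2, dtype=np.int16),
                       nodata=COUNT_NODATA)
        assert np.all(select(count, "preselect").values == 1)
        assert np.all(select(count, "final").values == 0)

    def test_three_selected_in_both_modes(self, grid):
        count = Raster(grid, np.full(grid.shape, 3, dtype=np.int16),
                       nodata=COUNT_NODATA)
        assert np.all(select(count, "preselect").values == 1)
        assert np.all(select(count, "final").values == 1)

    def test_final_equals_brute_force_and_on_random_stacks(self, grid):
        """Oracle equivalence: per-pixel loop over many random stacks."""
        rng = np.random.default_rng(12)
        for _ in range(25):
            stack = random_stack(grid, rng)
            count = criteria_count(stack)
            fin = select(count, "final").values
            pre = select(count, "preselect").values
            arrs = [np.asarray(m.values) for m in stack.masks]
            for r in range(grid.n_rows):
                for c in range(grid.n_cols):
                    met = sum(int(a[r, c] == 1) for a in arrs)
                    assert fin[r, c] == (1 if met == 3 else 0)
                    assert pre[r, c] == (1 if met >= 2 else 0)

    def test_monotone_in_mask_growth(self, grid):
        rng = np.random.default_rng(13)
        stack = random_stack(grid, rng)
        grown = [Raster(m.grid, m.values.copy(), nodata=255, band=m.band)
                 for m in stack.masks]
        grown[0].values[:] = np.maximum(grown[0].values, 1)  # enlarge one mask
        before = select(criteria_count(stack), "final").values
        after = select(criteria_count(CriteriaStack(masks=grown)), "final").values
        assert np.all(after >= before)

    def test_out_of_range_count_rejected(self, grid):
        count = Raster(grid, np.full(grid.shape, 4, dtype=np.int16),
                       nodata=COUNT_NODATA)
        with pytest.raises(ValueError):
            select(count, "final")
        with pytest.raises(ValueError):
            select(count, "everything")


def quadrant_regions():
    return RegionSet(regions=[
        ("NW", box(0, 1000, 1000, 2000)),
        ("NE", box(1000, 1000, 2000, 2000)),
        ("SW", box(0, 0, 1000, 1000)),
        ("SE", box(1000, 0, 2000, 1000)),
    ])


class TestZonalTabulate:
    def test_counts_and_areas_in_one_region(self, grid):
        vals = np.zeros(grid.shape, dtype=np.uint8)
        vals[:5, :5] = 1  # 25 pixels, all in NW
        rows = zonal_tabulate(Raster(grid, vals, nodata=255), quadrant_regions())
        d = {r["region"]: r for r in rows}
        assert d["NW"]["pixel_count"] == 25
        assert d["NW"]["area_km2"] == 25 * 0.01
        assert d["NE"]["pixel_count"] == 0
        assert d["_unassigned"]["pixel_count"] == 0

    def test_empty_mask_all_zero(self, grid):
        rows = zonal_tabulate(
            Raster(grid, np.zeros(grid.shape, dtype=np.uint8), nodata=255),
            quadrant_regions(),
        )
        assert all(r["pixel_count"] == 0 for r in rows)

    def test_conservation_with_partial_region_cover(self, grid):
        """Regions covering only part of the grid: counts + unassigned
        always equal the mask total."""
        rng = np.random.default_rng(14)
        vals = (rng.random(grid.shape) < 0.3).astype(np.uint8)
        regions = RegionSet(regions=[("west", box(0, 0, 900, 2000))])
        rows = zonal_tabulate(Raster(grid, vals, nodata=255), regions)
        assert sum(r["pixel_count"] for r in rows) == int(vals.sum())

    def test_boundary_center_assigned_to_exactly_one_region(self):
        """A center on the shared edge of two regions goes to the first."""
        g = GridSpec(CRS, 0.0, 100.0, 100.0, 100.0, 1, 1)  # center (50, 50)
        vals = np.ones((1, 1), dtype=np.uint8)
        regions = RegionSet(regions=[
            ("left", box(0, 0, 50, 100)),   # center on its right edge
            ("right", box(50, 0, 100, 100)),
        ])
        rows = zonal_tabulate(Raster(g, vals, nodata=255), regions)
        d = {r["region"]: r["pixel_count"] for r in rows}
        assert d["left"] == 1 and d["right"] == 0 and d["_unassigned"] == 0

    def test_duplicate_region_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            RegionSet(regions=[("A", box(0, 0, 1, 1)), ("A", box(1, 1, 2, 2))])

    def test_focus_area(self, grid):
        vals = np.zeros(grid.shape, dtype=np.uint8)
        vals[:5, :5] = 1
        area = focus_area_km2(Raster(grid, vals, nodata=255),
                              box(0, 1800, 300, 2000))  # rows 0-1, cols 0-2
        assert area == 6 * 0.01


class TestSummarize:
    def make_result(self, grid, vals, regions):
        mask = Raster(grid, vals, nodata=255, band="final_priority")
        table = zonal_tabulate(mask, regions)
        return PriorityResult(
            criteria_count=mask, preselection=mask, final=mask,
            region_table=table,
        )

    def test_report_counts_nonzero_regions_and_total(self, grid):
        vals = np.zeros(grid.shape, dtype=np.uint8)
        vals[2, 2] = 1   # NW
        vals[15, 15] = 1  # SE
        result = self.make_result(grid, vals, quadrant_regions())
        csv_text, text = summarize(result)
        assert "2 of 4 regions selected" in text
        assert "OK" in text
        assert csv_text.strip().splitlines()[-1] == "TOTAL,2,0.02"

    def test_all_zero_result(self, grid):
        vals = np.zeros(grid.shape, dtype=np.uint8)
        result = self.make_result(grid, vals, quadrant_regions())
        csv_text, text = summarize(result)
        assert "TOTAL,0,0" in csv_text
        assert "0 of 4 regions selected" in text

    def test_rows_sorted_by_area_descending(self, grid):
        vals = np.zeros(grid.shape, dtype=np.uint8)
        vals[:3, 12:18] = 1  # NE: 18 px
        vals[2, 2] = 1       # NW: 1 px
        result = self.make_result(grid, vals, quadrant_regions())
        csv_text, _ = summarize(result)
        lines = [l.split(",")[0] for l in csv_text.strip().splitlines()[1:]]
        assert lines[0] == "NE" and lines[1] == "NW"
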