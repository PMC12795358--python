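"""Grid model: alignment, area-weighted aggregation, thresholding, areas."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from firepriority.grid import (
    AlignmentError,
    GridSpec,
    Raster,
    aggregate_mean,
    check_aligned,
    mask_area_km2,
    pixel_area_km2,
    threshold_mask,
)


def brute_force_aggregate(fine: Raster, coarse: GridSpec) -> np.ndarray:
    """Independent oracle: double loop over fine cells, accumulating
    overlap-area-weighted sums into coarse cells."""
    num = np.zeros(coarse.shape)
    den = np.zeros(coarse.shape)
    fxe, fye = fine.grid.x_edges(), fine.grid.y_edges()
    cxe, cye = coarse.x_edges(), coarse.y_edges()
    bad = fine.nodata_mask()
    for i in range(fine.grid.n_rows):
        for j in range(fine.grid.n_cols):
            if bad[i, j]:
                continue
            for ci in range(coarse.n_rows):
                oy = min(fye[i], cye[ci]) - max(fye[i + 1], cye[ci + 1])
                if oy <= 0:
                    continue
                for cj in range(coarse.n_cols):
                    ox = min(fxe[j + 1], cxe[cj + 1]) - max(fxe[j], cxe[cj])
                    if ox <= 0:
                        continue
                    num[ci, cj] += ox * oy * fine.values[i, j]
                    den[ci, cj] += ox * oy
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


class TestAlignment:
    def test_identical_grids_align(self, grid500):
        assert check_aligned(grid500, grid500)

    def test_integer_offset_aligns(self, grid500):
        shifted = replace(grid500, origin_x=grid500.origin_x + 3 * 500.0,
                          origin_y=grid500.origin_y - 7 * 500.0)
        assert check_aligned(grid500, shifted)

    def test_half_cell_offset_misaligns(self, grid500):
        shifted = replace(grid500, origin_x=grid500.origin_x + 250.0)
        assert not check_aligned(grid500, shifted)

    def test_different_cell_sizes_misalign(self, grid500, grid30):
        assert not check_aligned(grid500, grid30)

    def test_different_crs_misaligns(self, grid500):
        other = replace(grid500, crs="EPSG:3035")
        assert not check_aligned(grid500, other)

    def test_alignment_is_equivalence_on_shifted_family(self, grid500):
        """Reflexive/symmetric/transitive across integer-shifted grids."""
        rng = np.random.default_rng(0)
        grids = [
            replace(
                grid500,
                origin_x=grid500.origin_x + int(k) * 500.0,
                origin_y=grid500.origin_y - int(m) * 500.0,
            )
            for k, m in rng.integers(-5, 5, size=(4, 2))
        ]
        for a in grids:
            assert check_aligned(a, a)
            for b in grids:
                assert check_aligned(a, b) == check_aligned(b, a)
                for c in grids:
                    if check_aligned(a, b) and check_aligned(b, c):
                        assert check_aligned(a, c)


class TestAggregateMean:
    def test_constant_field_is_preserved(self, grid30, grid500):
        coarse = replace(grid500, n_rows=6, n_cols=6)
        fine = Raster(grid30, np.full(grid30.shape, 4.25))
        out = aggregate_mean(fine, coarse)
        np.testing.assert_allclose(out.values, 4.25, rtol=1e-12)

    def test_half_covered_cell_is_half(self):
        """Coarse cell straddling a 1|0 split of fine cells -> 0.5."""
        fine_g = GridSpec("EPSG:2100", 0.0, 1000.0, 50.0, 50.0, 20, 20)
        coarse_g = GridSpec("EPSG:2100", 0.0, 1000.0, 500.0, 500.0, 2, 2)
        vals = np.zeros((20, 20))
        vals[:, :5] = 1.0  # left half of the left coarse cells
        out = aggregate_mean(Raster(fine_g, vals), coarse_g)
        np.testing.assert_allclose(out.values[:, 0], 0.5)
        np.testing.assert_allclose(out.values[:, 1], 0.0)

    def test_global_mean_conserved_against_brute_force(self):
        """Non-integer 500/30-style ratio: matches the double-loop oracle
        and conserves the global mean of a nodata-free field."""
        fine_g = GridSpec("EPSG:2100", 0.0, 1500.0, 30.0, 30.0, 50, 50)
        coarse_g = GridSpec("EPSG:2100", 0.0, 1500.0, 500.0, 500.0, 3, 3)
        rng = np.random.default_rng(42)
        vals = (rng.random((50, 50)) < 0.3).astype(float)
        fine = Raster(fine_g, vals)
        out = aggregate_mean(fine, coarse_g)
        np.testing.assert_allclose(out.values, brute_force_aggregate(fine, coarse_g),
                                   rtol=1e-9)
        np.testing.assert_allclose(np.mean(out.values), vals.mean(), rtol=1e-9)

    def test_nodata_fine_cells_excluded_and_all_nodata_propagates(self):
        fine_g = GridSpec("EPSG:2100", 0.0, 1000.0, 100.0, 100.0, 10, 10)
        coarse_g = GridSpec("EPSG:2100", 0.0, 1000.0, 500.0, 500.0, 2, 2)
        vals = np.ones((10, 10))
        vals[:5, :5] = np.nan       # top-left coarse cell entirely nodata
        vals[0, 5] = np.nan         # one bad cell elsewhere: just excluded
        out = aggregate_mean(Raster(fine_g, vals, nodata=float("nan")), coarse_g)
        assert np.isnan(out.values[0, 0])
        np.testing.assert_allclose(out.values[0, 1], 1.0)

    def test_crs_mismatch_and_not_coarser_rejected(self, grid30, grid500):
        fine = Raster(grid30, np.zeros(grid30.shape))
        with pytest.raises(AlignmentError):
            aggregate_mean(fine, replace(grid500, crs="EPSG:3035"))
        with pytest.raises(ValueError):
            aggregate_mean(fine, grid30)


class TestThresholdMask:
    def test_strict_boundary_excluded(self, grid500):
        vals = np.full(grid500.shape, 15.0)
        vals[0, 0] = 15.01
        out = threshold_mask(Raster(grid500, vals), 15.0, strict=True)
        assert out.values[0, 0] == 1
        assert out.values[1, 1] == 0

    def test_non_strict_boundary_included(self, grid500):
        vals = np.full(grid500.shape, 0.5)
        out = threshold_mask(Raster(grid500, vals), 0.5, strict=False)
        assert np.all(out.values == 1)

    def test_nodata_propagates(self, grid500):
        vals = np.full(grid500.shape, 20.0)
        vals[2, 3] = np.nan
        out = threshold_mask(Raster(grid500, vals, nodata=float("nan")), 15.0)
        assert out.values[2, 3] == 255
        assert out.nodata == 255

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(-100, 100), st.booleans())
    def test_idempotent_on_boolean_output(self, threshold, strict):
        g = GridSpec("EPSG:2100", 0.0, 100.0, 10.0, 10.0, 4, 4)
        rng = np.random.default_rng(1)
        first = threshold_mask(Raster(g, rng.normal(0, 50, g.shape) * 1.0),
                               threshold, strict=strict)
        again = threshold_mask(
            Raster(g, first.values.astype(float), nodata=255.0), 0.5, strict=False
        )
        np.testing.assert_array_equal(first.values, again.values)


class TestPixelArea:
    def test_500m_cell_is_quarter_km2(self, grid500):
        assert pixel_area_km2(grid500) == 0.25

    def test_30m_cell(self, grid30):
        assert pixel_area_km2(grid30) == pytest.approx(0.0009)

    def test_reported_total_is_integer_multiple_of_cell_area(self, grid500):
        """A 77.25 km2 total on a 500 m grid is exactly 309 pixels."""
        n = 77.25 / pixel_area_km2(grid500)
        assert n == pytest.approx(309)
        assert math.isclose(n, round(n))

    def test_geographic_crs_rejected(self):
        g = GridSpec("EPSG:4326", 20.0, 40.0, 0.005, 0.005, 10, 10)
        with pytest.raises(ValueError, match="reproject"):
            pixel_area_km2(g)

    def test_mask_area_counts_ones_only(self, grid500):
        vals = np.zeros(grid500.shape, dtype=np.uint8)
        vals[:3, :3] = 1
        vals[5, 5] = 255
        r = Raster(grid500, vals, nodata=255)
        assert mask_area_km2(r) == 9 * 0.25
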