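"""Grid I/O and preprocessing: ASCII/XYZ round-trips, aggregation, gap
filling, HAT cropping and the Horn slope operator."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra.numpy import arrays

from creekmorph.grid import (ElevationGrid, GridDataError, GridFormatError,
                             MarshMask, aggregate_to_resolution,
                             compute_slope_degrees, crop_to_marsh,
                             fill_nodata_nearest, grid_from_xyz, merge_grids,
                             read_ascii_grid, read_xyz, write_ascii_grid,
                             write_xyz)


def grid_of(values, cell=1.0, **kw):
    return ElevationGrid(values=np.asarray(values, dtype=float),
                         cell_size=cell, **kw)


# ---------------------------------------------------------------------------
# Esri ASCII
# ---------------------------------------------------------------------------

class TestAsciiGrid:
    def test_round_trip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        g = grid_of(np.round(rng.uniform(-5, 5, (7, 5)), 3), cell=2.0)
        g.origin_x, g.origin_y = 100.0, 250.0
        p = tmp_path / "g.asc"
        write_ascii_grid(g, p)
        back = read_ascii_grid(p)
        assert back.cell_size == 2.0
        assert back.origin_x == 100.0 and back.origin_y == 250.0
        np.testing.assert_array_equal(back.values, g.values)

    def test_center_origin_normalised_to_corner(self, tmp_path):
        p = tmp_path / "c.asc"
        p.write_text("ncols 2\nnrows 2\nxllcenter 0.5\nyllcenter 0.5\n"
                     "cellsize 1\n1 2\n3 4\n")
        g = read_ascii_grid(p)
        assert g.origin_x == 0.0 and g.origin_y == 0.0
        np.testing.assert_array_equal(g.values, [[1, 2], [3, 4]])

    def test_nodata_cell_flagged(self, tmp_path):
        p = tmp_path / "n.asc"
        p.write_text("ncols 2\nnrows 1\nxllcorner 0\nyllcorner 0\n"
                     "cellsize 1\nNODATA_value -9999\n-9999 2\n")
        g = read_ascii_grid(p)
        assert np.isnan(g.values[0, 0]) and g.values[0, 1] == 2.0

    @pytest.mark.parametrize("text,hint", [
        ("ncols 2\nnrows 1\nyllcorner 0\ncellsize 1\n1 2\n", "xllcorner"),
        ("ncols 2\nnrows 1\nxllcorner 0\nyllcorner 0\ncellsize x\n1 2\n",
         "cellsize"),
        ("nrows 1\nxllcorner 0\nyllcorner 0\ncellsize 1\n1 2\n", "ncols"),
    ])
    def test_malformed_header_names_key(self, tmp_path, text, hint):
        p = tmp_path / "bad.asc"
        p.write_text(text)
        with pytest.raises(GridFormatError, match=hint):
            read_ascii_grid(p)

    def test_row_length_mismatch_names_row(self, tmp_path):
        p = tmp_path / "bad.asc"
        p.write_text("ncols 3\nnrows 2\nxllcorner 0\nyllcorner 0\n"
                     "cellsize 1\n1 2 3\n4 5\n")
        with pytest.raises(GridFormatError, match="row 1"):
            read_ascii_grid(p)


class TestXyz:
    def test_cell_center_convention(self, tmp_path):
        g = grid_of([[2.5]])
        p = tmp_path / "a.xyz"
        write_xyz(g, MarshMask(values=np.ones((1, 1), bool)), p)
        assert p.read_text().strip() == "0.500 0.500 2.500"

    def test_nodata_cells_skipped(self, tmp_path):
        g = grid_of([[np.nan, 1.0]])
        p = tmp_path / "a.xyz"
        write_xyz(g, MarshMask(values=np.ones((1, 2), bool)), p)
        assert len(p.read_text().strip().splitlines()) == 1

    def test_empty_mask_errors(self, tmp_path):
        g = grid_of([[1.0]])
        with pytest.raises(GridDataError):
            write_xyz(g, MarshMask(values=np.zeros((1, 1), bool)),
                      tmp_path / "a.xyz")

    def test_round_trip_rebuild(self, tmp_path):
        rng = np.random.default_rng(1)
        g = grid_of(np.round(rng.uniform(0, 3, (6, 8)), 3), cell=1.0)
        mask = MarshMask(values=rng.random((6, 8)) > 0.3)
        mask.values[0, 0] = mask.values[-1, -1] = True  # pin the extent
        p = tmp_path / "a.xyz"
        write_xyz(g, mask, p)
        rebuilt = grid_from_xyz(read_xyz(p), cell_size=1.0)
        sel = mask.values
        np.testing.assert_allclose(rebuilt.values[sel], g.values[sel])


# ---------------------------------------------------------------------------
# Aggregation / merging
# ---------------------------------------------------------------------------

class TestAggregate:
    def test_block_mean(self):
        g = grid_of([[1, 1], [3, 3]], cell=0.5)
        out = aggregate_to_resolution(g, 1.0)
        assert out.values.shape == (1, 1) and out.values[0, 0] == 2.0
        assert out.cell_size == 1.0

    def test_nodata_excluded_from_block(self):
        g = grid_of([[2, 4], [6, np.nan]], cell=0.5)
        out = aggregate_to_resolution(g, 1.0)
        assert out.values[0, 0] == 4.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 2, (4, 4))
        vals[rng.random((4, 4)) < 0.2] = np.nan
        g = grid_of(vals, cell=0.25)
        out = aggregate_to_resolution(g, 0.5)
        # independent loop oracle
        for r in range(2):
            for c in range(2):
                block = vals[2 * r:2 * r + 2, 2 * c:2 * c + 2].ravel()
                block = block[np.isfinite(block)]
                want = block.mean() if block.size else np.nan
                got = out.values[r, c]
                assert (np.isnan(want) and np.isnan(got)) or \
                    math.isclose(got, want, rel_tol=1e-12)

    def test_conserves_count_weighted_mean(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 2, (8, 8))
        vals[rng.random((8, 8)) < 0.1] = np.nan
        g = grid_of(vals, cell=0.5)
        out = aggregate_to_resolution(g, 2.0)
        counts = np.zeros_like(out.values)
        for r in range(out.n_rows):
            for c in range(out.n_cols):
                block = vals[4 * r:4 * r + 4, 4 * c:4 * c + 4]
                counts[r, c] = np.isfinite(block).sum()
        fine_mean = np.nanmean(vals)
        coarse = np.nansum(out.values * counts) / counts.sum()
        assert math.isclose(coarse, fine_mean, rel_tol=1e-9)

    def test_non_integer_ratio_rejected(self):
        with pytest.raises(GridDataError):
            aggregate_to_resolution(grid_of(np.ones((4, 4)), cell=0.3), 1.0)


def test_merge_last_tile_wins():
    a = grid_of([[1.0, 1.0]], cell=1.0)
    b = grid_of([[2.0, 2.0]], cell=1.0)
    b.origin_x = 1.0
    merged = merge_grids([a, b])
    np.testing.assert_array_equal(merged.values, [[1.0, 2.0, 2.0]])


# ---------------------------------------------------------------------------
# Gap filling
# ---------------------------------------------------------------------------

class TestFillNodata:
    def test_single_gap_takes_neighbour(self):
        vals = np.full((3, 3), 5.0)
        vals[1, 1] = np.nan
        out = fill_nodata_nearest(grid_of(vals))
        assert out.values[1, 1] == 5.0

    def test_tie_breaks_row_first(self):
        # gap at (1,1): value 2 above at (0,1) and 7 right at (1,2), both
        # at distance 1 -> the smaller row index wins
        vals = np.full((3, 3), np.nan)
        vals[0, 1], vals[1, 2] = 2.0, 7.0
        out = fill_nodata_nearest(grid_of(vals))
        assert out.values[1, 1] == 2.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 2, (20, 20))
        vals[rng.random((20, 20)) < 0.1] = np.nan
        g = grid_of(vals)
        out = fill_nodata_nearest(g)
        vr, vc = np.nonzero(np.isfinite(vals))
        for r, c in zip(*np.nonzero(~np.isfinite(vals))):
            d2 = (vr - r) ** 2 + (vc - c) ** 2
            best = min((d2[i], vr[i], vc[i]) for i in range(len(vr)))
            assert out.values[r, c] == vals[best[1], best[2]]

    def test_preserves_valid_and_completes(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 2, (15, 15))
        vals[rng.random((15, 15)) < 0.2] = np.nan
        g = grid_of(vals)
        out = fill_nodata_nearest(g)
        valid = np.isfinite(vals)
        np.testing.assert_array_equal(out.values[valid], vals[valid])
        assert np.isfinite(out.values).all()

    def test_all_nodata_errors(self):
        with pytest.raises(GridDataError):
            fill_nodata_nearest(grid_of(np.full((3, 3), np.nan)))


# ---------------------------------------------------------------------------
# HAT cropping
# ---------------------------------------------------------------------------

class TestCropToMarsh:
    def test_excludes_seawall_ring(self):
        vals = np.full((10, 10), 2.0)
        vals[0, :] = vals[-1, :] = vals[:, 0] = vals[:, -1] = 6.0
        mask = crop_to_marsh(grid_of(vals), hat=4.9)
        assert mask.values[1:-1, 1:-1].all()
        assert not mask.values[0].any() and not mask.values[:, 0].any()

    def test_hat_below_minimum_errors(self):
        with pytest.raises(GridDataError, match="HAT"):
            crop_to_marsh(grid_of(np.full((4, 4), 2.0)), hat=1.0)

    def test_largest_basin_retained(self):
        vals = np.full((12, 12), 9.0)
        vals[1:6, 1:11] = 2.0   # 50 px basin
        vals[8:9, 2:9] = 2.0    # 7 px basin
        mask = crop_to_marsh(grid_of(vals), hat=4.0)
        assert mask.area_px == 50
        assert mask.values[1:6, 1:11].all()


# ---------------------------------------------------------------------------
# Slope (Horn 3x3)
# ---------------------------------------------------------------------------

class TestSlope:
    def test_constant_grid_is_flat(self):
        s = compute_slope_degrees(grid_of(np.full((5, 5), 3.0)))
        np.testing.assert_allclose(s.values, 0.0, atol=1e-12)

    def test_unit_plane_is_45_degrees(self):
        x = np.arange(8, dtype=float)
        g = grid_of(np.tile(x, (8, 1)))
        s = compute_slope_degrees(g)
        np.testing.assert_allclose(s.values[1:-1, 1:-1], 45.0, atol=1e-9)

    def test_hand_evaluated_horn_kernel(self):
        # asymmetric window: dz/dx and dz/dy evaluated by hand
        w = np.array([[0.0, 1.0, 3.0], [1.0, 2.0, 4.0], [2.0, 3.0, 5.0]])
        dzdx = ((3 + 2 * 4 + 5) - (0 + 2 * 1 + 2)) / 8.0   # 1.5
        dzdy = ((2 + 2 * 3 + 5) - (0 + 2 * 1 + 3)) / 8.0   # 1.0
        want = math.degrees(math.atan(math.hypot(dzdx, dzdy)))
        s = compute_slope_degrees(grid_of(w))
        assert math.isclose(s.values[1, 1], want, rel_tol=1e-12)

    def test_nodata_propagates_to_window(self):
        vals = np.full((5, 5), 1.0)
        vals[2, 2] = np.nan
        s = compute_slope_degrees(grid_of(vals))
        assert np.isnan(s.values[1:4, 1:4]).all()
        assert np.isfinite(s.values[0, 0])

    @given(arrays(float, (6, 6), elements=st.floats(-5, 5)),
           st.floats(-50, 50))
    def test_invariant_under_constant_offset(self, vals, c):
        a = compute_slope_degrees(grid_of(vals)).values
        b = compute_slope_degrees(grid_of(vals + c)).values
        np.testing.assert_allclose(a, b, atol=1e-8)

    @given(arrays(float, (6, 6), elements=st.floats(-5, 5)))
    def test_transpose_commutes(self, vals):
        a = compute_slope_degrees(grid_of(vals)).values
        b = compute_slope_degrees(grid_of(vals.T)).values
        np.testing.assert_allclose(a, b.T, atol=1e-9)
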