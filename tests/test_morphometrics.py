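"""Geometry, cross-sections, whole-network parameters, sensitivity and
elevation-change attribution."""

import math

import numpy as np
import pytest

from creekmorph.detect import CreekMask, DetectionConfig
from creekmorph.grid import ElevationGrid, GridDataError, MarshMask
from creekmorph.morphometrics import (SENSITIVITY_PARAMS, cross_section,
                                      elevation_change_vs_distance,
                                      junction_angle, opl_map,
                                      segment_cross_stats, segment_geometry,
                                      threshold_sensitivity)
from creekmorph.pipeline import extract
from creekmorph.synthetic import (MarshSpec, default_tides, generate_marsh,
                                  suggested_config)


class TestSegmentGeometry:
    def test_straight_path(self):
        path = [(5, c) for c in range(11)]
        sin, straight, ratio = segment_geometry(path, 1.0)
        assert (sin, straight, ratio) == (10.0, 10.0, 1.0)

    def test_right_angle_l(self):
        path = [(0, c) for c in range(6)] + [(r, 5) for r in range(1, 6)]
        sin, straight, ratio = segment_geometry(path, 1.0)
        assert sin == 10.0
        assert straight == pytest.approx(math.sqrt(50))
        assert ratio == pytest.approx(math.sqrt(2), rel=1e-12)

    def test_degenerate_path_rejected(self):
        with pytest.raises(GridDataError):
            segment_geometry([(0, 0)], 1.0)

    def test_sinuosity_at_least_one(self):
        rng = np.random.default_rng(0)
        path = [(0, 0)]
        for _ in range(30):
            dr, dc = rng.integers(-1, 2, 2)
            if (dr, dc) != (0, 0):
                path.append((path[-1][0] + dr, path[-1][1] + dc))
        if len(path) > 1:
            assert segment_geometry(path, 1.0)[2] >= 1.0


class TestJunctionAngle:
    def test_perpendicular_t_join(self):
        parent = [(10, c) for c in range(21)]  # downstream end first
        child = [(10 - i, 10) for i in range(8)]
        assert junction_angle(child, parent, (10, 10)) == pytest.approx(90.0)

    def test_doubling_back_approaches_180(self):
        # child hugs the parent's upstream chord, one row off
        parent = [(10, c) for c in range(21)]
        child = [(10, 10)] + [(9, 10 + i) for i in range(1, 7)]
        angle = junction_angle(child, parent, (10, 10))
        assert angle > 160.0

    def test_diagonal_tributary_vector_oracle(self):
        parent = [(10, c) for c in range(21)]
        child = [(10 - i, 10 + i) for i in range(8)]  # 45 deg, heading away
        angle = junction_angle(child, parent, (10, 10), fit_len=5)
        v_child = np.array([-5, 5])
        v_parent = np.array([0, -5])  # towards the parent's downstream end
        want = math.degrees(math.acos(
            v_child @ v_parent / (np.linalg.norm(v_child) *
                                  np.linalg.norm(v_parent))))
        assert angle == pytest.approx(want, abs=1e-9)
        assert angle == pytest.approx(135.0)


def channel_scene(profile):
    """A vertical channel of the given per-column elevation profile."""
    n = len(profile)
    vals = np.full((24, 24), 2.0)
    c0 = 12 - n // 2
    for i, z in enumerate(profile):
        vals[:, c0 + i] = z
    mask = np.zeros((24, 24), bool)
    mask[:, c0:c0 + n] = vals[:, c0:c0 + n] < 2.0
    grid = ElevationGrid(values=vals, cell_size=1.0)
    path = [(r, 12) for r in range(24)]
    return grid, CreekMask(values=mask), path


class TestCrossSection:
    def test_rectangular_channel(self):
        grid, mask, path = channel_scene([1.0, 1.0, 1.0])
        w, d, a = cross_section(grid, mask, path, 12)
        assert w == pytest.approx(3.0, abs=0.5)
        assert d == pytest.approx(1.0, abs=0.01)
        assert a == pytest.approx(3.0, abs=0.3)

    def test_v_channel_matches_analytic_triangle(self):
        grid, mask, path = channel_scene([1.5, 1.0, 1.5])
        w, d, a = cross_section(grid, mask, path, 12)
        # analytic triangle with banks 2.0, apex 1.0, half-width 2 cells
        assert a == pytest.approx(2.0, rel=0.10)
        assert d == pytest.approx(1.0, abs=0.01)

    def test_width_within_one_sample_step_of_oracle(self):
        profile = [1.2, 0.8, 0.6, 0.8, 1.2]
        grid, mask, path = channel_scene(profile)
        w, d, a = cross_section(grid, mask, path, 12)
        assert abs(w - 5.0) <= 0.5
        # oracle: integrate the cell-wise profile below the bank directly
        want_area = sum(2.0 - z for z in profile)
        assert a == pytest.approx(want_area, rel=0.1)

    def test_transect_leaving_grid_is_flagged(self):
        vals = np.full((10, 10), 1.0)
        mask = np.ones((10, 10), bool)  # creek mask covers everything
        grid = ElevationGrid(values=vals, cell_size=1.0)
        path = [(r, 5) for r in range(10)]
        assert cross_section(grid, CreekMask(values=mask), path, 5) is None


class TestCrossStats:
    def test_uniform_channel_matches_single_station(self):
        grid, mask, path = channel_scene([1.0, 1.0, 1.0])
        stats = segment_cross_stats(grid, mask, path, spacing=5)
        w, d, a = cross_section(grid, mask, path, 12)
        assert stats["mean_width"] == pytest.approx(w)
        assert stats["mean_depth"] == pytest.approx(d)
        assert stats["mean_xs_area"] == pytest.approx(a)

    def test_linearly_deepening_channel(self):
        vals = np.full((60, 20), 2.0)
        depth = np.linspace(0.5, 1.5, 60)
        for r in range(60):
            vals[r, 8:11] = 2.0 - depth[r]
        mask = np.zeros((60, 20), bool)
        mask[:, 8:11] = True
        grid = ElevationGrid(values=vals, cell_size=1.0)
        path = [(r, 9) for r in range(60)]
        stats = segment_cross_stats(grid, CreekMask(values=mask), path,
                                    spacing=5)
        assert stats["mean_depth"] == pytest.approx(1.0, rel=0.05)

    def test_short_segment_yields_none(self):
        grid, mask, path = channel_scene([1.0, 1.0, 1.0])
        stats = segment_cross_stats(grid, mask, path[:8], spacing=5,
                                    fit_len=5)
        assert stats["mean_width"] is None and stats["n_stations"] == 0


class TestOplMap:
    def test_edge_adjacent_cell_distance(self):
        marsh = MarshMask(values=np.ones((5, 5), bool))
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        d = opl_map(marsh, CreekMask(values=mask), cell_size=2.0)
        assert d[2, 3] == pytest.approx(2.0)
        assert d[2, 2] == 0.0
        assert d[0, 0] == pytest.approx(2.0 * math.sqrt(8))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        mask = rng.random((30, 30)) < 0.05
        mask[0, 0] = True
        marsh = MarshMask(values=np.ones((30, 30), bool))
        d = opl_map(marsh, CreekMask(values=mask), cell_size=1.0)
        mr, mc = np.nonzero(mask)
        for r in range(30):
            for c in range(30):
                want = np.sqrt(((mr - r) ** 2 + (mc - c) ** 2).min())
                assert d[r, c] == pytest.approx(want, abs=1e-9)

    def test_empty_mask_errors(self):
        with pytest.raises(GridDataError):
            opl_map(MarshMask(values=np.ones((4, 4), bool)),
                    CreekMask(values=np.zeros((4, 4), bool)), 1.0)


class TestNetworkSummary:
    def test_definitional_identities(self, small_marsh):
        spec, grid, marsh, truth, res = small_marsh
        m = res.metrics
        assert m.dd == pytest.approx(
            (m.tcl / 1000.0) / (m.catchment_area / 1e6), rel=1e-9)
        assert m.mcl <= m.tcl
        assert m.pa <= m.catchment_area
        assert m.sr >= 1.0
        assert m.nb == len(res.network.channels)
        # OPL equals the mean of the unchanneled-length map by definition
        d = opl_map(marsh, res.mask_repaired, grid.cell_size)
        non_creek = marsh.values & ~res.mask_repaired.values
        assert m.opl == pytest.approx(np.nanmean(d[non_creek]))

    def test_opl_zero_when_creek_covers_marsh(self):
        from creekmorph.morphometrics import network_summary
        from creekmorph.detect import SkeletonGrid
        from creekmorph.network import build_network, identify_outlets, \
            assign_reverse_strahler
        vals = np.full((10, 10), 1.0)
        grid = ElevationGrid(values=vals, cell_size=1.0)
        marsh = MarshMask(values=np.zeros((10, 10), bool))
        marsh.values[4:6, :] = True
        mask = CreekMask(values=marsh.values.copy())
        skel = np.zeros((10, 10), bool)
        skel[4, :] = True
        net = build_network(SkeletonGrid(values=skel))
        net = identify_outlets(net, marsh, mask, grid)
        net = assign_reverse_strahler(net)
        m = network_summary(grid, marsh, mask, net)
        assert m.opl == 0.0

    def test_main_channel_gradient_hand_computed(self):
        # straight channel, bed rising 0.8 -> 1.2 m over its length
        vals = np.full((30, 210), 2.0)
        bed = np.linspace(0.8, 1.2, 200)
        for i, z in enumerate(bed):
            vals[14:17, 5 + i] = z
        grid = ElevationGrid(values=vals, cell_size=1.0)
        marsh = MarshMask(values=np.ones((30, 210), bool))
        marsh.values[:, :5] = False   # seaward limit at the channel mouth
        cfg = DetectionConfig(z_thresh=1.5, s_thresh=75.0, min_component_px=5,
                              max_repair_dist=5.0)
        res = extract(grid, marsh, cfg)
        m = res.metrics
        z_mouth = grid.values[res.network.channels[0].pixel_path[0]]
        z_head = grid.values[res.network.channels[0].pixel_path[-1]]
        want = math.degrees(math.atan((z_head - z_mouth) / m.mcl))
        assert m.mcg == pytest.approx(want, rel=1e-9)
        assert m.mcg == pytest.approx(
            math.degrees(math.atan(0.4 / 200.0)), rel=0.1)

    def test_tidal_prism_of_uniform_channel(self, small_marsh):
        spec, grid, marsh, truth, res = small_marsh
        # creek volume should be close to the carved volume
        carved = sum(c.length * c.width * c.depth for c in truth.channels)
        assert res.metrics.tp == pytest.approx(carved, rel=0.35)


class TestSensitivity:
    def test_invariant_marsh_all_std_zero(self):
        spec = MarshSpec(noise_sigma=0.0, seed=0)
        grid, marsh, truth = generate_marsh(spec)
        cfg = suggested_config(spec)
        table = threshold_sensitivity(grid, marsh, cfg, tides=default_tides())
        assert len(table) == len(SENSITIVITY_PARAMS) == 12
        assert (table["Std"] == 0.0).all()
        assert table.attrs["failed_runs"] == []

    def test_std_matches_hand_computed_sample_std(self):
        # stepped channel: the detected creek shortens as z_thresh drops
        vals = np.full((30, 140), 2.0)
        vals[14:17, 0:90] = 1.0
        vals[14:17, 90:110] = 1.25
        vals[14:17, 110:130] = 1.42
        grid = ElevationGrid(values=vals, cell_size=1.0)
        marsh = MarshMask(values=np.ones((30, 140), bool))
        cfg = DetectionConfig(z_thresh=1.3, s_thresh=75.0, min_component_px=5,
                              max_repair_dist=0.0)
        tcls = []
        for off in (-0.15, 0.0, +0.15):
            c = DetectionConfig(z_thresh=1.3 + off, s_thresh=75.0,
                                min_component_px=5, max_repair_dist=0.0)
            tcls.append(extract(grid, marsh, c).metrics.tcl)
        assert tcls[0] < tcls[1] < tcls[2]
        table = threshold_sensitivity(grid, marsh, cfg)
        row = table[table["Symbol"] == "TCL"].iloc[0]
        want_std = np.std(tcls, ddof=1)
        assert row["Std"] == pytest.approx(want_std, abs=1e-6)
        assert row["Mean"] == pytest.approx(np.mean(tcls), abs=1e-6)
        assert row["Std (% of mean)"] == pytest.approx(
            100 * want_std / np.mean(tcls), abs=1e-6)

    def test_table_rows_match_parameter_suite(self):
        labels = [p[1] for p in SENSITIVITY_PARAMS]
        assert labels == ["MWS", "DD", "OPL", "MCL", "TCL", "NB", "CSA", "D",
                          "PA", "TP", "SR", "MCG"]


class TestElevationChange:
    def _grids(self, dz):
        base = np.full((40, 40), 2.0)
        g0 = ElevationGrid(values=base.copy(), cell_size=1.0)
        g1 = ElevationGrid(values=base + dz, cell_size=1.0)
        mask = np.zeros((40, 40), bool)
        mask[:, 19:22] = True
        marsh = MarshMask(values=np.ones((40, 40), bool))
        return g0, g1, marsh, CreekMask(values=mask), CreekMask(values=mask)

    def test_uniform_accretion(self):
        g0, g1, marsh, m0, m1 = self._grids(0.05)
        t = elevation_change_vs_distance(g0, g1, marsh, m0, m1)
        pos = t[t["sign"] == "positive"]
        assert np.allclose(pos[pos["n"] > 0]["mean_dz"], 0.05)
        assert (t[t["sign"] == "negative"]["n"] == 0).all()

    def test_no_change_all_bins_empty(self):
        g0, g1, marsh, m0, m1 = self._grids(0.0)
        t = elevation_change_vs_distance(g0, g1, marsh, m0, m1)
        assert (t["n"] == 0).all()

    def test_step_field_maps_to_distance_bins(self):
        g0, g1, marsh, m0, m1 = self._grids(0.0)
        from scipy import ndimage
        dist = ndimage.distance_transform_edt(~m1.values)
        dz = np.where(dist <= 5.0, 0.1, 0.02)
        g1 = ElevationGrid(values=g0.values + dz, cell_size=1.0)
        t = elevation_change_vs_distance(g0, g1, marsh, m0, m1)
        pos = t[(t["sign"] == "positive") & (t["n"] > 0)]
        for _, row in pos.iterrows():
            if row["distance_hi"] <= 5.0:
                assert row["mean_dz"] == pytest.approx(0.1)
            elif row["distance_lo"] >= 6.0:
                assert row["mean_dz"] == pytest.approx(0.02)

    def test_misregistered_grids_rejected(self):
        g0, g1, marsh, m0, m1 = self._grids(0.1)
        g1.origin_x = 5.0
        with pytest.raises(GridDataError, match="co-registered"):
            elevation_change_vs_distance(g0, g1, marsh, m0, m1)
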