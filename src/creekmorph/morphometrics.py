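"""Per-segment, per-order and whole-network creek morphometrics.

Computed quantities follow the standard creek-design parameter suite:
per segment/channel — sinuous length, straight length, sinuosity ratio,
junction angle and cross-sectional width, depth and area; per network —
drainage density (DD), overmarsh path length (OPL), main channel length
(MCL), total channel length (TCL), number of creeks (NB), total mouth
cross-sectional area (CSA), main channel mouth depth (D), planform area
(PA), undermarsh tidal prism / creek volume (TP), sinuosity ratio (SR) and
main channel gradient (MCG), plus the mean marsh elevation above MWS.

Also provides the threshold-sensitivity procedure (re-running the pipeline
with the elevation threshold perturbed by +/- the lidar vertical
resolution) and the elevation-change-vs-creek-distance attribution used to
analyse creek-forming processes between two survey epochs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import ndimage

from .detect import CreekMask, DetectionConfig
from .grid import ElevationGrid, GridDataError, MarshMask
from .network import CreekNetwork, NetworkError
from .tides import TidalLevels

__all__ = [
    "NetworkMetrics",
    "segment_geometry",
    "junction_angle",
    "cross_section",
    "segment_cross_stats",
    "channel_table",
    "order_table",
    "network_summary",
    "opl_map",
    "threshold_sensitivity",
    "elevation_change_vs_distance",
    "SENSITIVITY_PARAMS",
]

DEFAULT_FIT_LEN = 5
DEFAULT_SPACING = 5
MAX_TRANSECT_HALFWIDTH_PX = 100


@dataclass
class NetworkMetrics:
    """Whole-network parameter record."""

    dd: float  # drainage density (km/km^2)
    opl: float  # overmarsh path length (m)
    mcl: float  # main channel length (m)
    tcl: float  # total channel length (m)
    nb: int  # number of creeks (merged channels, all orders)
    csa: float  # total mouth cross-sectional area (m^2)
    d: float  # main channel mouth depth (m)
    pa: float  # planform area (m^2)
    tp: float  # undermarsh tidal prism / creek volume (m^3)
    sr: float  # length-weighted mean sinuosity ratio
    mcg: float  # main channel gradient (degrees, positive head-up)
    mean_elev_above_mws: float | None  # m
    catchment_area: float  # m^2

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _round_half_away(x: float) -> int:
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def segment_geometry(pixel_path, cell_size: float):
    """Sinuous length, straight length and sinuosity ratio of a pixel path.

    Sinuous length sums along-path steps (diagonals = sqrt(2) cells);
    straight length is the endpoint-to-endpoint distance, floored at one
    cell size so closed loops do not divide by zero.
    """
    if len(pixel_path) < 2:
        raise GridDataError("degenerate 1-pixel path has no geometry")
    steps = np.diff(np.asarray(pixel_path, dtype=float), axis=0)
    sinuous = float(np.hypot(steps[:, 0], steps[:, 1]).sum()) * cell_size
    a, b = pixel_path[0], pixel_path[-1]
    straight = float(np.hypot(a[0] - b[0], a[1] - b[1])) * cell_size
    straight = max(straight, cell_size)
    return sinuous, straight, sinuous / straight


def junction_angle(child_path, parent_path, junction,
                   fit_len: int = DEFAULT_FIT_LEN) -> float:
    """Angle (degrees) between a tributary and its parent's downstream chord.

    The child chord runs from the junction along the child's first
    ``fit_len`` pixels; the parent chord runs from the junction downstream
    (towards the parent's own mouth). 90 deg is a perpendicular join; values
    near 180 mean the child doubles back along the parent's upstream
    direction.
    """
    cp = child_path if child_path[0] == junction else list(reversed(child_path))
    ci = min(fit_len, len(cp) - 1)
    v_child = np.array(cp[ci]) - np.array(junction)
    try:
        j = parent_path.index(junction)
    except ValueError:
        raise GridDataError("junction pixel not on the parent path")
    pi = max(0, j - fit_len)
    if pi == j:  # junction at the parent's downstream end
        pi = min(len(parent_path) - 1, j + fit_len)
        v_parent = np.array(junction) - np.array(parent_path[pi])
    else:
        v_parent = np.array(parent_path[pi]) - np.array(junction)
    denom = np.linalg.norm(v_child) * np.linalg.norm(v_parent)
    if denom == 0:
        raise GridDataError("zero-length chord at junction")
    cosang = float(np.dot(v_child, v_parent)) / denom
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def cross_section(grid: ElevationGrid, mask: CreekMask, pixel_path,
                  station: int, fit_len: int = DEFAULT_FIT_LEN):
    """Width (m), depth (m) and area (m^2) of one channel transect.

    The transect runs through the station pixel perpendicular to the local
    centreline chord (+/- ``fit_len`` pixels), sampled every half cell until
    it leaves the creek mask on both sides. The bank level is the mean
    elevation of the two first out-of-mask (marsh) cells; depth is bank
    level minus the transect's minimum bed elevation; area integrates
    max(0, bank - z) across the in-mask samples. Returns None when the
    transect exits the grid, runs away, or meets nodata — the station is
    flagged and skipped by callers.
    """
    n = len(pixel_path)
    if not 0 <= station < n:
        raise GridDataError(f"station {station} outside the pixel path")
    a = np.array(pixel_path[max(0, station - fit_len)], dtype=float)
    b = np.array(pixel_path[min(n - 1, station + fit_len)], dtype=float)
    t = b - a
    norm = np.hypot(*t)
    if norm == 0:
        return None
    normal = np.array([-t[1], t[0]]) / norm
    center = np.array(pixel_path[station], dtype=float)
    cell = grid.cell_size
    step = 0.5  # strip width, in cells

    def march(direction: float):
        """Sample half-cell strips outward from the centreline.

        Strip j covers ((j)*step, (j+1)*step] and is sampled at its
        midpoint; returns (n_in_strips, bank_z, in-mask z list) or None.
        """
        zs = []
        for j in range(2 * MAX_TRANSECT_HALFWIDTH_PX):
            pos = center + direction * normal * (j + 0.5) * step
            r = _round_half_away(pos[0])
            c = _round_half_away(pos[1])
            if not (0 <= r < grid.n_rows and 0 <= c < grid.n_cols):
                return None  # exits grid before exiting mask
            if not mask.values[r, c]:
                bank = grid.values[r, c]
                if not np.isfinite(bank):
                    return None
                return j, float(bank), zs
            z = grid.values[r, c]
            if not np.isfinite(z):
                return None
            zs.append(float(z))
        return None

    left = march(+1.0)
    right = march(-1.0)
    if left is None or right is None:
        return None
    j_l, bank_l, zs_l = left
    j_r, bank_r, zs_r = right
    if not zs_l and not zs_r:
        return None  # station pixel itself out of mask: degenerate transect
    bank = 0.5 * (bank_l + bank_r)
    in_mask = zs_l + zs_r
    width = (j_l + j_r) * step * cell
    depth = bank - min(in_mask)
    ds = step * cell
    area = sum(max(0.0, bank - z) for z in in_mask) * ds
    return width, depth, area


def segment_cross_stats(grid: ElevationGrid, mask: CreekMask, pixel_path,
                        spacing: int = DEFAULT_SPACING,
                        fit_len: int = DEFAULT_FIT_LEN):
    """Mean width, depth and cross-sectional area over regular stations.

    Stations sit every ``spacing`` pixels, excluding ``fit_len`` pixels at
    either end (junction-contaminated transects). Returns a dict with the
    means, the number of valid stations and the number skipped; means are
    None when no station is valid.
    """
    n = len(pixel_path)
    stations = list(range(fit_len, n - fit_len, spacing))
    ws, ds, ars = [], [], []
    skipped = 0
    for s in stations:
        xs = cross_section(grid, mask, pixel_path, s, fit_len=fit_len)
        if xs is None:
            skipped += 1
            continue
        w, d, a = xs
        ws.append(w); ds.append(d); ars.append(a)
    if not ws:
        return {"mean_width": None, "mean_depth": None, "mean_xs_area": None,
                "n_stations": 0, "n_skipped": skipped}
    return {"mean_width": float(np.mean(ws)), "mean_depth": float(np.mean(ds)),
            "mean_xs_area": float(np.mean(ars)), "n_stations": len(ws),
            "n_skipped": skipped}


def channel_table(grid: ElevationGrid, mask: CreekMask, net: CreekNetwork,
                  spacing: int = DEFAULT_SPACING,
                  fit_len: int = DEFAULT_FIT_LEN) -> pd.DataFrame:
    """Per-channel metrics: geometry, junction angle and cross-sections."""
    rows = []
    for cid in sorted(net.channels):
        ch = net.channels[cid]
        sin, straight, ratio = segment_geometry(ch.pixel_path, net.cell_size)
        angle = np.nan
        if ch.parent_id is not None:
            parent = net.channels[ch.parent_id]
            angle = junction_angle(ch.pixel_path, parent.pixel_path,
                                   ch.junction, fit_len=fit_len)
        stats = segment_cross_stats(grid, mask, ch.pixel_path,
                                    spacing=spacing, fit_len=fit_len)
        rows.append({
            "channel_id": cid, "order": ch.order, "component": ch.component,
            "sinuous_length": sin, "straight_length": straight,
            "sinuosity_ratio": ratio, "junction_angle": angle,
            "mean_width": stats["mean_width"],
            "mean_depth": stats["mean_depth"],
            "mean_xs_area": stats["mean_xs_area"],
            "n_stations": stats["n_stations"],
            "n_skipped": stats["n_skipped"],
        })
    return pd.DataFrame(rows)


APPENDIX_COLUMNS = [
    "Reverse Strahler order", "Number of creeks per order", "Total Length",
    "Mean Length", "Bifurcation Ratio", "Sinuosity Ratio",
    "Mean junction angle", "Mean channel width", "Mean channel depth",
    "Mean cross-sectional area", "A/D", "W/D",
]


def order_table(channels: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a channel table into per-reverse-Strahler-order statistics.

    Bifurcation ratio for order k is N(k+1)/N(k) (NaN for the highest
    order); A/D is mean area over mean depth squared (a mean width/depth
    measure) and W/D the mean width over mean depth.
    """
    if channels.empty:
        return pd.DataFrame(columns=APPENDIX_COLUMNS)
    rows = []
    counts = channels.groupby("order").size()
    for order in sorted(counts.index):
        sub = channels[channels["order"] == order]
        n = int(counts[order])
        n_next = int(counts.get(order + 1, 0))
        mean_depth = sub["mean_depth"].dropna().mean()
        mean_area = sub["mean_xs_area"].dropna().mean()
        mean_width = sub["mean_width"].dropna().mean()
        rows.append({
            "Reverse Strahler order": order,
            "Number of creeks per order": n,
            "Total Length": sub["sinuous_length"].sum(),
            "Mean Length": sub["sinuous_length"].mean(),
            "Bifurcation Ratio": (n_next / n) if n_next else np.nan,
            "Sinuosity Ratio": sub["sinuosity_ratio"].mean(),
            "Mean junction angle": sub["junction_angle"].dropna().mean(),
            "Mean channel width": mean_width,
            "Mean channel depth": mean_depth,
            "Mean cross-sectional area": mean_area,
            "A/D": mean_area / mean_depth**2 if mean_depth else np.nan,
            "W/D": mean_width / mean_depth if mean_depth else np.nan,
        })
    return pd.DataFrame(rows)


def opl_map(marsh: MarshMask, mask: CreekMask, cell_size: float) -> np.ndarray:
    """Euclidean distance (m) to the nearest creek pixel, over the marsh.

    The per-cell unchanneled-length map; NaN outside the marsh. Its mean
    over in-marsh non-creek cells is the overmarsh path length (OPL).
    """
    if not mask.values.any():
        raise GridDataError("empty creek mask: distances are undefined")
    dist = ndimage.distance_transform_edt(~mask.values) * cell_size
    out = np.where(marsh.values, dist, np.nan)
    return out


def network_summary(grid: ElevationGrid, marsh: MarshMask, mask: CreekMask,
                    net: CreekNetwork,
                    tides: TidalLevels | None = None) -> NetworkMetrics:
    """Whole-network parameters from an ordered creek network."""
    cell = net.cell_size
    area_m2 = marsh.area_m2(cell)
    tcl = sum(s.length for s in net.segments.values() if s.order is not None)
    dd = (tcl / 1000.0) / (area_m2 / 1e6)
    dist = opl_map(marsh, mask, cell)
    non_creek = marsh.values & ~mask.values
    opl = float(np.nanmean(dist[non_creek])) if non_creek.any() else 0.0

    mcl = 0.0
    mcg = float("nan")
    if net.outlets:
        comp = net.outlets[0].component
        main = [c for c in net.channels.values()
                if c.component == comp and c.order == 1]
        if main:
            main_ch = main[0]
            mcl = main_ch.length
            z_mouth = grid.values[main_ch.pixel_path[0]]
            z_head = grid.values[main_ch.pixel_path[-1]]
            if np.isfinite(z_mouth) and np.isfinite(z_head) and mcl > 0:
                mcg = float(np.degrees(np.arctan((z_head - z_mouth) / mcl)))

    nb = len(net.channels)
    csa = float(sum(o.area for o in net.outlets))
    d = net.outlets[0].depth if net.outlets else float("nan")
    pa = mask.n_pixels * cell**2

    # Tidal prism: per creek pixel, the bank reference is the elevation of
    # the nearest non-creek marsh cell (local bank-top convention).
    bank_src = marsh.values & ~mask.values & grid.valid
    tp = 0.0
    if bank_src.any() and mask.values.any():
        _, (ir, ic) = ndimage.distance_transform_edt(~bank_src,
                                                     return_indices=True)
        cr, cc = np.nonzero(mask.values)
        bank_ref = grid.values[ir[cr, cc], ic[cr, cc]]
        z = grid.values[cr, cc]
        ok = np.isfinite(bank_ref) & np.isfinite(z)
        tp = float(np.maximum(0.0, bank_ref[ok] - z[ok]).sum() * cell**2)

    lengths = np.array([c.length for c in net.channels.values()])
    if lengths.size:
        sins = np.array([segment_geometry(c.pixel_path, cell)[2]
                         for c in net.channels.values()])
        sr = float((lengths * sins).sum() / lengths.sum())
    else:
        sr = float("nan")

    mean_above_mws = None
    if tides is not None:
        in_marsh = marsh.values & grid.valid
        mean_above_mws = float(np.mean(grid.values[in_marsh]) - tides.mws)

    return NetworkMetrics(dd=dd, opl=opl, mcl=mcl, tcl=tcl, nb=nb, csa=csa,
                          d=d, pa=pa, tp=tp, sr=sr, mcg=mcg,
                          mean_elev_above_mws=mean_above_mws,
                          catchment_area=area_m2)


#: Table-4-style parameter rows reported by the sensitivity analysis.
SENSITIVITY_PARAMS = [
    ("Mean elevation above MWS (m)", "MWS", "mean_elev_above_mws"),
    ("Drainage density (km/km^2)", "DD", "dd"),
    ("Overmarsh path length (m)", "OPL", "opl"),
    ("Main channel length (m)", "MCL", "mcl"),
    ("Total channel length (m)", "TCL", "tcl"),
    ("Number of creeks (no unit)", "NB", "nb"),
    ("Total mouth cross-sectional area (m^2)", "CSA", "csa"),
    ("Main channel mouth depth (m)", "D", "d"),
    ("Planform area (m^2)", "PA", "pa"),
    ("Undermarsh tidal prism (creek volume) (m^3)", "TP", "tp"),
    ("Sinuosity ratio (no unit)", "SR", "sr"),
    ("Main channel gradient (deg)", "MCG", "mcg"),
]


def threshold_sensitivity(grid: ElevationGrid, marsh: MarshMask,
                          cfg: DetectionConfig,
                          tides: TidalLevels | None = None,
                          delta: float | None = None,
                          offsets=None, **pipeline_kwargs) -> pd.DataFrame:
    """Detection uncertainty: re-run with the elevation threshold perturbed.

    The pipeline is re-run with z_thresh shifted by each offset (default
    {-delta, 0, +delta} with delta = cfg.z_tolerance, the lidar vertical
    resolution). Per parameter the sample standard deviation (n-1) over the
    runs and its percentage of the mean are reported. Runs yielding an empty
    network are excluded and counted in the table attrs.
    """
    from .pipeline import extract  # lazy: pipeline builds on this module

    if delta is None:
        delta = cfg.z_tolerance
    if offsets is None:
        offsets = (-delta, 0.0, +delta)
    records = []
    failed = []
    for off in offsets:
        cfg_i = DetectionConfig(z_thresh=cfg.z_thresh + off,
                                s_thresh=cfg.s_thresh,
                                min_component_px=cfg.min_component_px,
                                max_repair_dist=cfg.max_repair_dist,
                                z_tolerance=cfg.z_tolerance)
        try:
            res = extract(grid, marsh, cfg_i, tides=tides, **pipeline_kwargs)
            records.append((off, res.metrics.to_dict()))
        except (GridDataError, NetworkError) as exc:
            failed.append((off, str(exc)))
    rows = []
    for label, symbol, key in SENSITIVITY_PARAMS:
        vals = [rec[key] for _, rec in records
                if rec.get(key) is not None and np.isfinite(rec[key])]
        if len(vals) >= 2:
            mean = float(np.mean(vals))
            # identical runs report exactly zero spread
            std = 0.0 if max(vals) == min(vals) \
                else float(np.std(vals, ddof=1))
            pct = 100.0 * std / abs(mean) if mean != 0 else np.nan
        else:
            mean = vals[0] if vals else np.nan
            std = pct = np.nan
        rows.append({"Parameter": label, "Symbol": symbol, "Mean": mean,
                     "Std": std, "Std (% of mean)": pct})
    table = pd.DataFrame(rows)
    table.attrs["offsets"] = list(offsets)
    table.attrs["failed_runs"] = failed
    return table


def elevation_change_vs_distance(grid_t0: ElevationGrid,
                                 grid_t1: ElevationGrid,
                                 marsh: MarshMask,
                                 mask_t0: CreekMask, mask_t1: CreekMask,
                                 max_dist: float = 20.0,
                                 bin_width: float = 1.0) -> pd.DataFrame:
    """Attribute elevation change to creek proximity between two epochs.

    Per in-marsh cell, dz = z(t1) - z(t0). Accreting cells (dz > 0) are
    binned by distance to the MOST RECENT creek extent; eroding cells
    (dz < 0) by distance to the INITIAL creek extent, in ``bin_width`` bins
    up to ``max_dist`` (default 20 m, limiting the confounding influence of
    site elevation and of multiple creeks). Returns one row per (sign, bin)
    with mean dz and the cell count.
    """
    if grid_t0.values.shape != grid_t1.values.shape or \
            not math.isclose(grid_t0.cell_size, grid_t1.cell_size) or \
            not math.isclose(grid_t0.origin_x, grid_t1.origin_x, abs_tol=1e-6) or \
            not math.isclose(grid_t0.origin_y, grid_t1.origin_y, abs_tol=1e-6):
        raise GridDataError("epoch grids are not co-registered")
    cell = grid_t0.cell_size
    dz = grid_t1.values - grid_t0.values
    valid = marsh.values & np.isfinite(dz)
    dist0 = ndimage.distance_transform_edt(~mask_t0.values) * cell
    dist1 = ndimage.distance_transform_edt(~mask_t1.values) * cell
    edges = np.arange(0.0, max_dist + bin_width, bin_width)
    rows = []
    for sign, sel, dist in (("positive", valid & (dz > 0), dist1),
                            ("negative", valid & (dz < 0), dist0)):
        d = dist[sel]
        v = dz[sel]
        for lo, hi in zip(edges[:-1], edges[1:]):
            in_bin = (d >= lo) & (d < hi)
            n = int(in_bin.sum())
            rows.append({
                "sign": sign, "distance_lo": lo, "distance_hi": hi,
                "mean_dz": float(v[in_bin].mean()) if n else np.nan,
                "n": n,
            })
    return pd.DataFrame(rows)
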