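"""Parametric synthetic marsh DEMs with known creek ground truth.

Emulates the structure the detection algorithm assumes: a flat marsh
platform ringed by a seawall, breached at the seaward edge, with a
dendritic creek tree carved below the platform from each breach — creeks
lie lower than the surrounding marsh and have steep edges. Lidar-like
Gaussian vertical noise and nodata speckle can be added on top. Every
channel's centreline, width, depth, order and length are recorded before
noise, so each pipeline stage can be checked against ground truth.

What this generator does NOT emulate: residual water in creek beds (the
carved creeks are dry, so depths are fully observable), vegetation bias,
and gradual bank profiles — recovery tests on these surfaces bound
algorithmic error only, not sensor effects.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .detect import DetectionConfig
from .grid import ElevationGrid, MarshMask
from .tides import TidalLevels

__all__ = [
    "MarshSpec",
    "GroundTruthChannel",
    "GroundTruth",
    "generate_marsh",
    "degrade",
    "default_tides",
    "suggested_config",
]

#: Lidar-like vertical noise (m): the vertical resolution of airborne lidar.
DEFAULT_NOISE_SIGMA = 0.15


@dataclass
class MarshSpec:
    """Parameters of a synthetic marsh with carved dendritic creeks.

    The defaults describe a 300 m x 300 m managed-realignment-like scheme at
    the standard 1 m working resolution: a 2 m ODN platform behind a 6 m
    seawall with one southern breach, and a depth-3 binary creek tree whose
    widths, depths and segment lengths shrink with increasing reverse-
    Strahler order.
    """

    extent: tuple[float, float] = (300.0, 300.0)  # (width, height) m
    cell_size: float = 1.0
    platform_elevation: float = 2.0
    seawall_height: float = 4.0  # wall top = platform + seawall_height
    wall_thickness_px: int = 3
    breach_x: tuple[float, ...] = (150.0,)  # breach centres on the south edge
    branching_factor: int = 2
    tree_depth: int = 3  # maximum reverse-Strahler order
    order_widths: tuple[float, ...] = (5.0, 4.0, 3.0)  # m, per order
    order_depths: tuple[float, ...] = (1.2, 1.0, 0.8)  # m, per order
    order_lengths: tuple[float, ...] = (220.0, 60.0, 22.0)  # m, per order
    attach_fractions: tuple[float, ...] = (0.3, 0.55)
    branch_angle_deg: float = 45.0
    sinuosity_amplitude: float = 0.0  # meander amplitude (cells)
    sinuosity_wavelength: float = 60.0  # meander wavelength (cells)
    cross_profile: str = "rectangular"  # or "parabolic"
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    nodata_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        k = self.tree_depth
        for name in ("order_widths", "order_depths", "order_lengths"):
            if len(getattr(self, name)) < k:
                raise ValueError(f"{name} must list at least {k} values")
        for seq in (self.order_widths[:k], self.order_depths[:k]):
            if any(b > a for a, b in zip(seq, seq[1:])):
                raise ValueError(
                    "widths and depths must not increase with order")
        for bx in self.breach_x:
            if not 0 < bx < self.extent[0]:
                raise ValueError(f"breach at x={bx} outside the {self.extent} "
                                 "m extent")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 <= self.nodata_fraction < 1:
            raise ValueError("nodata_fraction must lie in [0, 1)")


@dataclass
class GroundTruthChannel:
    order: int
    polyline: list  # (row, col) vertices, downstream end first
    width: float
    depth: float
    length: float  # m, along the polyline


@dataclass
class GroundTruth:
    channels: list
    creek_mask: np.ndarray  # pre-noise boolean carved extent
    marsh_mask: np.ndarray
    cell_size: float

    @property
    def tcl(self) -> float:
        return sum(c.length for c in self.channels)

    @property
    def dd(self) -> float:
        area_m2 = self.marsh_mask.sum() * self.cell_size**2
        return (self.tcl / 1000.0) / (area_m2 / 1e6)

    def order_counts(self) -> dict:
        counts: dict[int, int] = {}
        for c in self.channels:
            counts[c.order] = counts.get(c.order, 0) + 1
        return counts

    def to_json(self, path) -> None:
        from pathlib import Path

        payload = {
            "cell_size": self.cell_size,
            "tcl": self.tcl,
            "dd": self.dd,
            "order_counts": {str(k): v for k, v in
                             sorted(self.order_counts().items())},
            "channels": [
                {"order": c.order, "width": c.width, "depth": c.depth,
                 "length": c.length,
                 "polyline": [[float(r), float(col)] for r, col in c.polyline]}
                for c in self.channels
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def default_tides() -> TidalLevels:
    """Plausible macrotidal levels (m ODN) bracketing the default platform."""
    return TidalLevels(hat=4.9, mhws=4.3, mhwn=3.5, mws=1.5, mlwn=0.5,
                       mlws=-0.5)


def suggested_config(spec: MarshSpec) -> DetectionConfig:
    """Detection thresholds that separate the carved creeks by construction.

    The elevation threshold sits halfway between the platform and the
    shallowest channel bed. The slope threshold is set above the seawall-toe
    slope (the steepest non-creek feature on these surfaces), so detection
    is driven by the elevation criterion and recovered widths match the
    carved widths.
    """
    k = spec.tree_depth
    min_depth = min(spec.order_depths[:k])
    return DetectionConfig(
        z_thresh=spec.platform_elevation - min_depth / 2.0,
        s_thresh=75.0,
        min_component_px=10,
        max_repair_dist=5.0,
    )


def _channel_polyline(start, direction, length_px, spec: MarshSpec):
    """Vertices of one channel centreline in continuous (row, col) space."""
    n = max(int(math.ceil(length_px)), 2)
    s = np.linspace(0.0, length_px, n + 1)
    d = np.asarray(direction, dtype=float)
    d /= np.hypot(*d)
    perp = np.array([-d[1], d[0]])
    pts = np.asarray(start, dtype=float)[None, :] + s[:, None] * d[None, :]
    if spec.sinuosity_amplitude > 0:
        off = spec.sinuosity_amplitude * np.sin(
            2 * np.pi * s / spec.sinuosity_wavelength)
        pts = pts + off[:, None] * perp[None, :]
    return pts


def _polyline_length(pts) -> float:
    d = np.diff(pts, axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def _build_tree(spec: MarshSpec, n_rows: int, n_cols: int):
    """Lay out the channel polylines of every breach's tree, in pixels."""
    cell = spec.cell_size
    channels: list[GroundTruthChannel] = []

    def grow(start, direction, order, side):
        length_px = spec.order_lengths[order - 1] / cell
        pts = _channel_polyline(start, direction, length_px, spec)
        channels.append(GroundTruthChannel(
            order=order, polyline=[tuple(p) for p in pts],
            width=spec.order_widths[order - 1],
            depth=spec.order_depths[order - 1],
            length=_polyline_length(pts) * cell))
        if order >= spec.tree_depth:
            return
        ang = math.radians(spec.branch_angle_deg)
        d = np.asarray(direction, dtype=float)
        d /= np.hypot(*d)
        fracs = spec.attach_fractions[: spec.branching_factor]
        for i, frac in enumerate(fracs):
            idx = int(round(frac * (len(pts) - 1)))
            attach = pts[idx]
            sgn = 1.0 if (i + side) % 2 == 0 else -1.0
            ca, sa = math.cos(sgn * ang), math.sin(sgn * ang)
            child_dir = (d[0] * ca - d[1] * sa, d[0] * sa + d[1] * ca)
            grow(attach, child_dir, order + 1, side + i)

    for bx in spec.breach_x:
        col = bx / cell
        start = (float(n_rows - 1), col)  # south edge, heading north
        grow(start, (-1.0, 0.0), 1, 0)
    return channels


def _validate_tree(channels: list) -> None:
    """Longest-path sanity: a parent must out-reach every child subtree so
    generated orders coincide with reverse-Strahler orders, and channels
    must stay inside the domain."""
    by_order: dict[int, list[GroundTruthChannel]] = {}
    for c in channels:
        by_order.setdefault(c.order, []).append(c)
    max_order = max(by_order)
    # subtree reach per channel, bottom-up (children attach to the channel
    # of the previous order whose polyline passes nearest their start)
    reach = {id(c): c.length for c in channels}
    for order in range(max_order - 1, 0, -1):
        for parent in by_order[order]:
            ppts = np.asarray(parent.polyline)
            seg = np.cumsum(np.r_[0.0, np.hypot(*np.diff(ppts, axis=0).T)])
            for child in by_order.get(order + 1, []):
                c0 = np.asarray(child.polyline[0])
                d2 = ((ppts - c0) ** 2).sum(axis=1)
                if d2.min() > 1.0:
                    continue  # attaches to a different parent
                j = int(np.argmin(d2))
                remaining = seg[-1] - seg[j]
                if reach[id(child)] >= remaining:
                    raise ValueError(
                        "tree spec error: a child subtree out-reaches the "
                        "remaining parent channel; generated orders would "
                        "not be reverse-Strahler orders")
                reach[id(parent)] = max(reach[id(parent)],
                                        seg[j] + reach[id(child)])


def _carve(z: np.ndarray, channels: list, spec: MarshSpec) -> np.ndarray:
    """Carve channels into the surface; deepest channel wins per cell.
    Returns the carved-extent boolean mask."""
    carved = np.zeros(z.shape, dtype=bool)
    for ch in channels:
        pts = np.asarray(ch.polyline)
        # densify so no cell is skipped
        dense = [pts[0]]
        for a, b in zip(pts[:-1], pts[1:]):
            n = max(int(np.hypot(*(b - a)) / 0.25), 1)
            for i in range(1, n + 1):
                dense.append(a + (b - a) * i / n)
        dense = np.asarray(dense)
        half = ch.width / spec.cell_size / 2.0
        r0 = max(int(np.floor(dense[:, 0].min() - half)) - 1, 0)
        r1 = min(int(np.ceil(dense[:, 0].max() + half)) + 2, z.shape[0])
        c0 = max(int(np.floor(dense[:, 1].min() - half)) - 1, 0)
        c1 = min(int(np.ceil(dense[:, 1].max() + half)) + 2, z.shape[1])
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1),
                             indexing="ij")
        cells = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
        from scipy.spatial import cKDTree

        tree = cKDTree(dense)
        dist, _ = tree.query(cells, k=1)
        inside = dist <= half
        rows = rr.ravel()[inside]
        cols = cc.ravel()[inside]
        if spec.cross_profile == "parabolic":
            rel = (dist[inside] / half) ** 2
            bed = spec.platform_elevation - ch.depth * (1.0 - rel)
        else:
            bed = np.full(rows.shape, spec.platform_elevation - ch.depth)
        z[rows, cols] = np.minimum(z[rows, cols], bed)
        carved[rows, cols] = True
    return carved


def generate_marsh(spec: MarshSpec):
    """Build the synthetic marsh.

    Returns ``(ElevationGrid, MarshMask, GroundTruth)``. The DEM is a
    platform ringed by a seawall, breached where each creek tree's entry
    channel crosses the south wall; Gaussian noise and nodata speckle are
    applied after the ground truth is recorded. Same seed, same output,
    bit for bit.
    """
    cell = spec.cell_size
    n_cols = int(round(spec.extent[0] / cell))
    n_rows = int(round(spec.extent[1] / cell))
    z = np.full((n_rows, n_cols), spec.platform_elevation)
    w = spec.wall_thickness_px
    wall_top = spec.platform_elevation + spec.seawall_height
    wall = np.zeros((n_rows, n_cols), dtype=bool)
    wall[:w, :] = wall[-w:, :] = True
    wall[:, :w] = wall[:, -w:] = True
    z[wall] = wall_top

    channels = _build_tree(spec, n_rows, n_cols)
    _validate_tree(channels)
    for ch in channels:
        pts = np.asarray(ch.polyline)
        half = ch.width / cell / 2.0
        inner = ~((pts[:, 0] > w + half) & (pts[:, 0] < n_rows - 1 - w) &
                  (pts[:, 1] > w + half) & (pts[:, 1] < n_cols - w - half))
        if ch.order > 1 and inner.any():
            raise ValueError("tree spec error: a tributary reaches the "
                             "seawall; shrink lengths or move breaches")
    carved = _carve(z, channels, spec)

    marsh = ~wall | carved
    truth = GroundTruth(channels=channels, creek_mask=carved,
                        marsh_mask=marsh.copy(), cell_size=cell)

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        z = z + rng.normal(0.0, spec.noise_sigma, z.shape)
    if spec.nodata_fraction > 0:
        gaps = rng.random(z.shape) < spec.nodata_fraction
        z = z.copy()
        z[gaps] = np.nan
    grid = ElevationGrid(values=z, cell_size=cell)
    return grid, MarshMask(values=marsh), truth


def degrade(grid: ElevationGrid, gap_fraction: float,
            seed: int) -> ElevationGrid:
    """Knock random cells out to nodata (remnant-water-like gaps)."""
    if not 0 <= gap_fraction < 1:
        raise ValueError("gap_fraction must lie in [0, 1)")
    out = grid.copy()
    if gap_fraction == 0:
        return out
    rng = np.random.default_rng(seed)
    gaps = rng.random(out.values.shape) < gap_fraction
    out.values[gaps] = np.nan
    return out
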