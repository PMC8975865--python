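"""Creek detection: thresholding, noise removal, repair and thinning.

A creek network is a connected feature lying lower than the surrounding
marsh platform, with edges delimited by a steeper slope. Detection therefore
combines an elevation threshold with a slope threshold; small disconnected
speckle is removed, fragmented terminal channels are reconnected along
straight (Bresenham) repair paths, and the repaired mask is thinned to a
single-pixel centreline skeleton.

All mask operations use 8-connectivity: diagonally touching channel pixels
belong to one creek.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.draw import line as bresenham_line
from skimage.morphology import skeletonize as _zhang_thin

from .grid import EIGHT_CONNECTED, ElevationGrid, GridDataError, MarshMask, SlopeGrid

__all__ = [
    "DetectionConfig",
    "CreekMask",
    "SkeletonGrid",
    "detect_creek_mask",
    "filter_small_components",
    "reconnect_fragments",
    "skeletonize",
    "prune_spurs",
]

#: Default vertical perturbation for threshold-sensitivity runs (m): the
#: vertical resolution of airborne lidar.
DEFAULT_Z_TOLERANCE = 0.15


@dataclass
class DetectionConfig:
    """The four user thresholds of the detection pipeline.

    z_thresh
        Elevation (m) at or below which cells are creek candidates.
    s_thresh
        Slope (degrees) at or above which cells mark creek edges.
    min_component_px
        Connected elements smaller than this pixel count are noise.
    max_repair_dist
        Cap (m) on the straight repair path reconnecting a fragment.
    z_tolerance
        +/- perturbation (m) applied to z_thresh in sensitivity runs.
    """

    z_thresh: float
    s_thresh: float = 40.0
    min_component_px: int = 10
    max_repair_dist: float = 5.0
    z_tolerance: float = DEFAULT_Z_TOLERANCE

    def __post_init__(self) -> None:
        if not 0 < self.s_thresh < 90:
            raise ValueError(f"s_thresh must lie in (0, 90), got {self.s_thresh}")
        if self.min_component_px < 1:
            raise ValueError("min_component_px must be >= 1")
        if self.max_repair_dist < 0:
            raise ValueError("max_repair_dist must be >= 0")
        if self.z_tolerance < 0:
            raise ValueError("z_tolerance must be >= 0")


@dataclass
class CreekMask:
    """Boolean creek-pixel grid with a provenance stage label."""

    values: np.ndarray
    provenance: str = "raw"  # raw | filtered | repaired
    detached: list = field(default_factory=list)  # fragments left unrepaired

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.values.sum())


@dataclass
class SkeletonGrid:
    """Single-pixel-wide centreline of a repaired creek mask."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)


def _label(mask: np.ndarray):
    return ndimage.label(mask, structure=EIGHT_CONNECTED)


def detect_creek_mask(grid: ElevationGrid, slope: SlopeGrid, marsh: MarshMask,
                      cfg: DetectionConfig) -> CreekMask:
    """Threshold detection of the raw creek mask.

    Candidates are in-marsh cells that are low (z <= z_thresh) or steep
    (slope >= s_thresh). An 8-connected candidate component is retained only
    if it contains at least one elevation-qualified cell; slope-only
    components (seawall toes, marsh-edge scarps) are dropped.
    """
    if grid.values.shape != marsh.values.shape or \
            slope.values.shape != grid.values.shape:
        raise GridDataError("grid, slope and marsh mask are not co-registered")
    low = marsh.values & grid.valid & (grid.values <= cfg.z_thresh)
    with np.errstate(invalid="ignore"):
        steep = marsh.values & np.isfinite(slope.values) & \
            (slope.values >= cfg.s_thresh)
    cand = low | steep
    out = np.zeros_like(cand)
    if cand.any():
        labels, n = _label(cand)
        qualified = np.unique(labels[low])
        qualified = qualified[qualified > 0]
        out = np.isin(labels, qualified)
    if not out.any():
        warnings.warn("creek detection produced an empty mask", stacklevel=2)
    return CreekMask(values=out, provenance="raw")


def filter_small_components(mask: CreekMask,
                            min_component_px: int) -> CreekMask:
    """Remove 8-connected components smaller than ``min_component_px``."""
    labels, n = _label(mask.values)
    if n == 0:
        return CreekMask(values=mask.values.copy(), provenance="filtered")
    counts = np.bincount(labels.ravel())
    keep = counts >= min_component_px
    keep[0] = False
    return CreekMask(values=keep[labels], provenance="filtered")


def reconnect_fragments(mask: CreekMask, cfg: DetectionConfig,
                        cell_size: float = 1.0) -> CreekMask:
    """Reconnect fragmented channels to the trunk along straight bridges.

    The largest component is the trunk. Iteratively, the fragment with the
    smallest minimum pixel-to-trunk Euclidean distance (ties broken by the
    fragment pixel's row, then column) is joined by rasterizing the straight
    Bresenham segment between the closest pixel pair, provided that distance
    does not exceed ``max_repair_dist`` (in metres). Later fragments may
    attach to earlier bridges. Out-of-reach fragments are left detached and
    reported on the returned mask.
    """
    values = mask.values.copy()
    labels, n = _label(values)
    if n <= 1:
        return CreekMask(values=values, provenance="repaired")
    counts = np.bincount(labels.ravel())
    trunk_label = int(np.argmax(counts[1:])) + 1
    trunk = labels == trunk_label
    fragments = {}
    for lab in range(1, n + 1):
        if lab != trunk_label:
            fragments[lab] = np.column_stack(np.nonzero(labels == lab))
    detached: list[np.ndarray] = []
    max_d2 = (cfg.max_repair_dist / cell_size) ** 2
    while fragments:
        trunk_px = np.column_stack(np.nonzero(trunk))
        tree = cKDTree(trunk_px)
        # Closest pixel pair per fragment, deterministic tie-breaks in d^2.
        best = None  # (d2, frag_r, frag_c, trunk_r, trunk_c, label)
        for lab, px in sorted(fragments.items()):
            d, idx = tree.query(px, k=1)
            # exact integer squared distances
            d2 = (px[:, 0] - trunk_px[idx, 0]) ** 2 + \
                 (px[:, 1] - trunk_px[idx, 1]) ** 2
            d2min = int(d2.min())
            for i in np.nonzero(d2 == d2min)[0]:
                fr, fc = int(px[i, 0]), int(px[i, 1])
                cand = tree.query_ball_point((fr, fc), np.sqrt(d2min) + 1e-6)
                for j in cand:
                    tr, tc = int(trunk_px[j, 0]), int(trunk_px[j, 1])
                    if (fr - tr) ** 2 + (fc - tc) ** 2 != d2min:
                        continue
                    key = (d2min, fr, fc, tr, tc)
                    if best is None or key < best[:5]:
                        best = (*key, lab)
        d2min, fr, fc, tr, tc, lab = best
        if d2min > max_d2 + 1e-9:
            # nearest fragment is out of reach, hence so are all others
            # w.r.t. the current trunk: stop and report them all.
            for lab2, px in sorted(fragments.items()):
                detached.append(px)
            break
        rr, cc = bresenham_line(fr, fc, tr, tc)
        trunk[rr, cc] = True
        values[rr, cc] = True
        frag_px = fragments.pop(lab)
        trunk[frag_px[:, 0], frag_px[:, 1]] = True
    out = CreekMask(values=values, provenance="repaired", detached=detached)
    return out


def skeletonize(mask: CreekMask) -> SkeletonGrid:
    """Topology-preserving morphological thinning to a 1-px centreline.

    Zhang-style thinning, followed by a deterministic cleanup pass removing
    redundant pixels from any remaining 2x2 all-true block (scanning in row,
    column order and only deleting simple points), so the skeleton is
    strictly thin while the component count of the input mask is preserved.
    """
    skel = _zhang_thin(mask.values)
    skel = _remove_2x2_blocks(skel)
    return SkeletonGrid(values=skel)


_NEIGHBOR_CYCLE = [(-1, 0), (-1, 1), (0, 1), (1, 1),
                   (1, 0), (1, -1), (0, -1), (-1, -1)]


def _is_simple(skel: np.ndarray, r: int, c: int) -> bool:
    """True if removing (r, c) preserves local 8-topology (crossing number 1)
    and the pixel is not an endpoint."""
    nb = []
    n_rows, n_cols = skel.shape
    for dr, dc in _NEIGHBOR_CYCLE:
        rr, cc = r + dr, c + dc
        nb.append(bool(skel[rr, cc]) if 0 <= rr < n_rows and 0 <= cc < n_cols
                  else False)
    count = sum(nb)
    if count < 2:
        return False
    transitions = sum(1 for i in range(8) if not nb[i] and nb[(i + 1) % 8])
    return transitions == 1


def _remove_2x2_blocks(skel: np.ndarray) -> np.ndarray:
    """Deterministically delete redundant pixels of 2x2 all-true blocks.

    Pixels that are simple points (crossing number 1) go first; around
    junction blobs where no block pixel is locally simple, a pixel is
    removed if the global 8-connected component count is unchanged (this
    may open a micro-loop, but never splits a creek).
    """
    skel = skel.copy()
    changed = True
    while changed:
        changed = False
        blocks = skel[:-1, :-1] & skel[1:, :-1] & skel[:-1, 1:] & skel[1:, 1:]
        if not blocks.any():
            break
        n_comp = ndimage.label(skel, structure=EIGHT_CONNECTED)[1]
        for r, c in zip(*np.nonzero(blocks)):
            for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
                rr, cc = r + dr, c + dc
                if skel[rr, cc] and _is_simple(skel, rr, cc):
                    skel[rr, cc] = False
                    changed = True
                    break
            if changed:
                break
            for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
                rr, cc = r + dr, c + dc
                if not skel[rr, cc]:
                    continue
                skel[rr, cc] = False
                if ndimage.label(skel, structure=EIGHT_CONNECTED)[1] == n_comp:
                    changed = True
                    break
                skel[rr, cc] = True
            if changed:
                break
    return skel


def _degree_map(skel: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    return ndimage.convolve(skel.astype(int), kernel, mode="constant") * skel


def prune_spurs(skel: SkeletonGrid, min_len_px: int = 5) -> SkeletonGrid:
    """Remove short terminal spurs left by thinning.

    A spur is a branch from an endpoint to the first junction pixel whose
    along-pixel length (diagonal steps = sqrt(2)) is below ``min_len_px``.
    Whole components that are bare endpoint-to-endpoint lines are never
    pruned. Iterates until stable; endpoints are processed in (row, column)
    order for determinism.
    """
    values = skel.values.copy()
    while True:
        deg = _degree_map(values)
        endpoints = sorted(zip(*np.nonzero(deg == 1)))
        removed_any = False
        for r, c in endpoints:
            if not values[r, c] or deg[r, c] != 1:
                continue
            path = [(r, c)]
            length = 0.0
            prev = None
            cur = (r, c)
            hit_junction = False
            while True:
                nxt = None
                for dr, dc in _NEIGHBOR_CYCLE:
                    rr, cc = cur[0] + dr, cur[1] + dc
                    if 0 <= rr < values.shape[0] and 0 <= cc < values.shape[1] \
                            and values[rr, cc] and (rr, cc) != prev \
                            and (rr, cc) not in path:
                        nxt = (rr, cc)
                        break
                if nxt is None:
                    break
                step = np.hypot(nxt[0] - cur[0], nxt[1] - cur[1])
                if deg[nxt] >= 3:
                    hit_junction = True
                    length += step
                    break
                length += step
                path.append(nxt)
                prev, cur = cur, nxt
                if deg[cur] == 1:  # bare line: other endpoint reached
                    break
            if hit_junction and length < min_len_px:
                for rr, cc in path:
                    values[rr, cc] = False
                removed_any = True
                deg = _degree_map(values)
        if not removed_any:
            break
    return SkeletonGrid(values=values)
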