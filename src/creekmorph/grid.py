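"""Gridded elevation data: Esri ASCII / XYZ I/O and DEM preprocessing.

The preprocessing chain mirrors the standard workflow for lidar-derived
marsh DEMs: merge tiles, aggregate to a 1 m working resolution, fill data
gaps by nearest-neighbour interpolation, crop the study area to the
intertidal zone below the local Highest Astronomical Tide (HAT), and derive
a slope map in degrees.

Conventions
-----------
* Row 0 is the NORTH-most row (Esri ASCII grid order); ``(x, y)`` of a cell
  refers to its centre; exported coordinates are cell centres.
* Missing data are stored as NaN in memory; the ``nodata`` attribute is the
  sentinel used when writing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "ElevationGrid",
    "MarshMask",
    "SlopeGrid",
    "GridFormatError",
    "GridDataError",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_xyz",
    "write_xyz",
    "grid_from_xyz",
    "merge_grids",
    "aggregate_to_resolution",
    "fill_nodata_nearest",
    "crop_to_marsh",
    "compute_slope_degrees",
]

#: 8-connectivity structuring element used for all mask labelling.
EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)

DEFAULT_NODATA = -9999.0

#: Sanity bound on |z| for a coastal DEM relative to ordnance datum (m).
PLAUSIBLE_ELEVATION_BOUND = 100.0


class GridFormatError(ValueError):
    """A file does not conform to the expected grid dialect."""


class GridDataError(ValueError):
    """Grid contents violate an operation's preconditions."""


@dataclass
class ElevationGrid:
    """A rectangular grid of elevations (m) on a projected CRS.

    ``values`` uses NaN for missing cells; ``nodata`` is the sentinel written
    to disk. ``origin_x, origin_y`` locate the LOWER-LEFT corner of the grid
    while row 0 of ``values`` is the northern-most row.
    """

    values: np.ndarray
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise GridDataError("elevation values must be a 2-D array")
        if not self.cell_size > 0:
            raise GridDataError(f"cell_size must be positive, got {self.cell_size}")
        # Normalise any sentinel values that slipped in to NaN.
        self.values[self.values == self.nodata] = np.nan

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def valid(self) -> np.ndarray:
        """Boolean array marking non-nodata cells."""
        return np.isfinite(self.values)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(x, y) of a cell centre; row 0 is the northern-most row."""
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        """Per-row y centres, row 0 first (north to south)."""
        rows = np.arange(self.n_rows)
        return self.origin_y + (self.n_rows - rows - 0.5) * self.cell_size

    def check_plausible(self, bound: float = PLAUSIBLE_ELEVATION_BOUND) -> None:
        z = self.values[self.valid]
        if z.size and np.abs(z).max() >= bound:
            raise GridDataError(
                f"elevations exceed plausibility bound |z| < {bound} m "
                f"(max |z| = {np.abs(z).max():.2f})"
            )

    def copy(self) -> "ElevationGrid":
        return replace(self, values=self.values.copy())


@dataclass
class MarshMask:
    """Boolean grid marking the studied marsh (catchment) area."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)

    @property
    def area_px(self) -> int:
        return int(self.values.sum())

    def area_m2(self, cell_size: float) -> float:
        return self.area_px * cell_size**2


@dataclass
class SlopeGrid:
    """Slope in degrees (0-90), registered to its source ElevationGrid."""

    values: np.ndarray
    cell_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = np.isfinite(self.values)
        if finite.any():
            v = self.values[finite]
            if v.min() < 0 or v.max() > 90:
                raise GridDataError("slope values must lie in [0, 90] degrees")


# ---------------------------------------------------------------------------
# Esri ASCII grid I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = {"ncols", "nrows", "xllcorner", "xllcenter", "yllcorner",
                "yllcenter", "cellsize", "nodata_value"}


def read_ascii_grid(path) -> ElevationGrid:
    """Read an Esri ASCII grid (.asc).

    Header keys are case-insensitive; ``xllcenter/yllcenter`` origins are
    normalised to the lower-left *corner* convention; a missing
    ``NODATA_value`` defaults to -9999.
    """
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if not parts:
            continue
        key = parts[0].lower()
        if key not in _HEADER_KEYS:
            break
        if len(parts) != 2:
            raise GridFormatError(f"malformed header line for key '{parts[0]}'")
        try:
            header[key] = float(parts[1])
        except ValueError as exc:
            raise GridFormatError(
                f"header key '{parts[0]}' has non-numeric value '{parts[1]}'"
            ) from exc
    for required in ("ncols", "nrows", "cellsize"):
        if required not in header:
            raise GridFormatError(f"missing required header key '{required}'")
    if not ({"xllcorner", "xllcenter"} & header.keys()):
        raise GridFormatError("missing required header key 'xllcorner'")
    if not ({"yllcorner", "yllcenter"} & header.keys()):
        raise GridFormatError("missing required header key 'yllcorner'")

    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    cell = header["cellsize"]
    if cell <= 0:
        raise GridFormatError("header key 'cellsize' must be positive")
    # Centre-origin headers locate the centre of the lower-left cell.
    ox = header.get("xllcorner", header.get("xllcenter", 0.0) - cell / 2.0)
    oy = header.get("yllcorner", header.get("yllcenter", 0.0) - cell / 2.0)
    nodata = header.get("nodata_value", DEFAULT_NODATA)

    data_lines = [ln for ln in lines[i:] if ln.split()]
    if len(data_lines) != nrows:
        raise GridFormatError(
            f"expected {nrows} data rows, found {len(data_lines)}"
        )
    rows = []
    for r, line in enumerate(data_lines):
        vals = line.split()
        if len(vals) != ncols:
            raise GridFormatError(
                f"row {r} has {len(vals)} values, expected {ncols}"
            )
        rows.append([float(v) for v in vals])
    values = np.asarray(rows, dtype=float)
    return ElevationGrid(values=values, cell_size=cell, origin_x=ox,
                         origin_y=oy, nodata=nodata)


def write_ascii_grid(grid: ElevationGrid, path, precision: int = 3) -> None:
    """Write an Esri ASCII grid; NaN cells become the nodata sentinel."""
    out = []
    out.append(f"ncols {grid.n_cols}")
    out.append(f"nrows {grid.n_rows}")
    out.append(f"xllcorner {grid.origin_x:.{precision}f}")
    out.append(f"yllcorner {grid.origin_y:.{precision}f}")
    out.append(f"cellsize {grid.cell_size:.{precision}f}")
    out.append(f"NODATA_value {grid.nodata:g}")
    fmt = f"%.{precision}f"
    for row in grid.values:
        cells = [("%g" % grid.nodata) if not math.isfinite(v) else (fmt % v)
                 for v in row]
        out.append(" ".join(cells))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# XYZ text I/O (one "x y z" line per exported cell centre)
# ---------------------------------------------------------------------------

def write_xyz(grid: ElevationGrid, mask: MarshMask, path,
              precision: int = 3) -> None:
    """Export masked, non-nodata cells as "x y z" lines in row-major order."""
    if mask.values.shape != grid.values.shape:
        raise GridDataError("grid and mask shapes differ")
    sel = mask.values & grid.valid
    if not sel.any():
        raise GridDataError("nothing to export: mask selects no valid cell")
    rows, cols = np.nonzero(sel)
    xs = grid.origin_x + (cols + 0.5) * grid.cell_size
    ys = grid.origin_y + (grid.n_rows - rows - 0.5) * grid.cell_size
    zs = grid.values[rows, cols]
    fmt = f"%.{precision}f %.{precision}f %.{precision}f"
    lines = [fmt % (x, y, z) for x, y, z in zip(xs, ys, zs)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path) -> np.ndarray:
    """Read an XYZ text file into an (N, 3) float array."""
    pts = []
    for n, line in enumerate(Path(path).read_text().splitlines()):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 3:
            raise GridFormatError(f"XYZ line {n} has {len(parts)} fields, expected 3")
        pts.append([float(p) for p in parts])
    if not pts:
        raise GridFormatError("XYZ file contains no points")
    return np.asarray(pts, dtype=float)


def grid_from_xyz(points: np.ndarray, cell_size: float,
                  nodata: float = DEFAULT_NODATA) -> ElevationGrid:
    """Rebuild an ElevationGrid from cell-centre XYZ points.

    Points must lie on a regular lattice of the given cell size; cells with
    no point become nodata.
    """
    points = np.asarray(points, dtype=float)
    x, y, z = points[:, 0], points[:, 1], points[:, 2]
    ox = x.min() - cell_size / 2.0
    oy = y.min() - cell_size / 2.0
    cols = np.round((x - ox) / cell_size - 0.5).astype(int)
    rows_from_bottom = np.round((y - oy) / cell_size - 0.5).astype(int)
    n_rows = rows_from_bottom.max() + 1
    n_cols = cols.max() + 1
    values = np.full((n_rows, n_cols), np.nan)
    values[n_rows - 1 - rows_from_bottom, cols] = z
    return ElevationGrid(values=values, cell_size=cell_size, origin_x=ox,
                         origin_y=oy, nodata=nodata)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def merge_grids(grids: list[ElevationGrid]) -> ElevationGrid:
    """Mosaic same-resolution tiles into one grid.

    Tiles are processed in the given order; where tiles overlap, the LAST
    tile's value wins. Tile origins must be co-registered (offset by integer
    multiples of the cell size).
    """
    if not grids:
        raise GridDataError("no grids to merge")
    cell = grids[0].cell_size
    for g in grids:
        if not math.isclose(g.cell_size, cell, rel_tol=1e-9):
            raise GridDataError("cannot merge grids with differing cell sizes")
    ox = min(g.origin_x for g in grids)
    oy = min(g.origin_y for g in grids)
    top = max(g.origin_y + g.n_rows * g.cell_size for g in grids)
    right = max(g.origin_x + g.n_cols * g.cell_size for g in grids)
    n_cols = int(round((right - ox) / cell))
    n_rows = int(round((top - oy) / cell))
    values = np.full((n_rows, n_cols), np.nan)
    for g in grids:
        c0 = int(round((g.origin_x - ox) / cell))
        r0 = int(round((top - (g.origin_y + g.n_rows * cell)) / cell))
        if not (math.isclose(c0 * cell, g.origin_x - ox, abs_tol=1e-6 * cell)
                and math.isclose(r0 * cell, top - g.origin_y - g.n_rows * cell,
                                 abs_tol=1e-6 * cell)):
            raise GridDataError("tile origins are not co-registered")
        block = values[r0:r0 + g.n_rows, c0:c0 + g.n_cols]
        valid = g.valid
        block[valid] = g.values[valid]
    return ElevationGrid(values=values, cell_size=cell, origin_x=ox,
                         origin_y=oy, nodata=grids[0].nodata)


def aggregate_to_resolution(grid: ElevationGrid,
                            target_cell: float) -> ElevationGrid:
    """Block-mean aggregation to a coarser, nested resolution.

    ``target_cell`` must be an integer multiple of the input cell size. Each
    output cell is the mean of its block's non-nodata inputs; fully-nodata
    blocks stay nodata. The grid is anchored at its north-west corner;
    trailing partial blocks average whatever cells they cover.
    """
    ratio = target_cell / grid.cell_size
    factor = int(round(ratio))
    if factor < 1 or abs(ratio - factor) > 1e-9:
        raise GridDataError(
            f"target cell {target_cell} is not an integer multiple of "
            f"{grid.cell_size}"
        )
    if factor == 1:
        return grid.copy()
    nr = -(-grid.n_rows // factor)
    nc = -(-grid.n_cols // factor)
    padded = np.full((nr * factor, nc * factor), np.nan)
    padded[: grid.n_rows, : grid.n_cols] = grid.values
    blocks = padded.reshape(nr, factor, nc, factor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        values = np.nanmean(blocks, axis=(1, 3))
    top = grid.origin_y + grid.n_rows * grid.cell_size
    return ElevationGrid(values=values, cell_size=target_cell,
                         origin_x=grid.origin_x,
                         origin_y=top - nr * target_cell,
                         nodata=grid.nodata)


def fill_nodata_nearest(grid: ElevationGrid,
                        mask: MarshMask | None = None) -> ElevationGrid:
    """Fill in-mask nodata cells from the Euclidean-nearest valid in-mask cell.

    Pure nearest-neighbour assignment (no averaging), which preserves sharp
    channel edges. Ties in distance are broken deterministically: smallest
    row index first, then smallest column. Cells outside the mask are left
    untouched.
    """
    sel = np.ones(grid.values.shape, dtype=bool) if mask is None else mask.values
    valid = grid.valid & sel
    gaps = sel & ~grid.valid
    if not valid.any():
        raise GridDataError("cannot fill gaps: no valid cell inside the mask")
    out = grid.copy()
    if not gaps.any():
        return out
    vr, vc = np.nonzero(valid)
    src = np.column_stack([vr, vc])
    tree = cKDTree(src)
    gr, gc = np.nonzero(gaps)
    targets = np.column_stack([gr, gc])
    dists, _ = tree.query(targets, k=1)
    for (r, c), d in zip(targets, dists):
        # All candidate distances are sqrt of integers; compare exactly in d^2.
        cand = tree.query_ball_point((r, c), d + 1e-6)
        d2 = (src[cand, 0] - r) ** 2 + (src[cand, 1] - c) ** 2
        d2min = d2.min()
        best = min(
            (tuple(src[i]) for i, dd in zip(cand, d2) if dd == d2min)
        )
        out.values[r, c] = grid.values[best]
    return out


def crop_to_marsh(grid: ElevationGrid, hat: float,
                  boundary=None) -> MarshMask:
    """Delimit the studied marsh: cells below the local HAT level.

    The landward limit of the intertidal zone is the HAT contour; an optional
    seaward/seawall ``boundary`` polygon (shapely Polygon or sequence of
    (x, y) ring vertices) further restricts the area. Only the largest
    8-connected region is retained — the scheme's catchment.
    """
    sel = grid.valid & (grid.values < hat)
    if boundary is not None:
        import shapely

        poly = boundary if hasattr(boundary, "contains") else shapely.Polygon(boundary)
        xs = grid.x_centers()
        ys = grid.y_centers()
        xx, yy = np.meshgrid(xs, ys)
        inside = shapely.contains_xy(poly, xx.ravel(), yy.ravel())
        sel &= inside.reshape(sel.shape)
    if not sel.any():
        zmin = np.nanmin(grid.values) if grid.valid.any() else float("nan")
        zmax = np.nanmax(grid.values) if grid.valid.any() else float("nan")
        raise GridDataError(
            f"no cells below HAT={hat} m (grid range {zmin:.2f}..{zmax:.2f} m)"
        )
    labels, n = ndimage.label(sel, structure=EIGHT_CONNECTED)
    if n > 1:
        counts = np.bincount(labels.ravel())[1:]
        keep = int(np.argmax(counts)) + 1  # ties: first label = deterministic
        sel = labels == keep
    return MarshMask(values=sel)


# Horn 3x3 kernel offsets: letters a..i over the window,
#   a b c
#   d e f
#   g h i
def compute_slope_degrees(grid: ElevationGrid) -> SlopeGrid:
    """Slope map in degrees from the Horn 3x3 finite-difference operator.

    Edge cells use reflected padding; any window containing a nodata cell
    yields nodata.
    """
    if grid.n_rows < 3 or grid.n_cols < 3:
        raise GridDataError("slope requires at least a 3x3 grid")
    z = np.pad(grid.values, 1, mode="reflect")
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2];                  f = z[1:-1, 2:]
    g = z[2:, :-2];  h = z[2:, 1:-1];  i = z[2:, 2:]
    cell = grid.cell_size
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cell)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * cell)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    slope[~grid.valid] = np.nan
    return SlopeGrid(values=slope, cell_size=cell)
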