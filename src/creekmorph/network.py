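"""Creek network graph: segments, outlets, and reverse-Strahler ordering.

The skeleton is converted to a graph whose nodes are endpoint pixels
(1 neighbour) and junction pixels (>= 3 neighbours) and whose edges are
maximal 8-connected pixel chains. Outlets — the creek mouths at seawall
breaches or the seaward marsh edge — are endpoints nearest to creek-mask
pixels on the marsh boundary.

Reverse-Strahler ordering makes the entry channel order 1 (the reverse of
classic headwater-first Strahler ordering): the order-1 channel is the
longest sinuous path from the largest outlet; pruning it leaves stumps whose
own longest paths from their junctions become order-2 channels, and so on
recursively. Ties in path length are broken by larger mean cross-sectional
area, then by (row, column) of the far endpoint, so ordering is fully
deterministic.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy import ndimage

from .detect import SkeletonGrid, CreekMask, _degree_map, _NEIGHBOR_CYCLE
from .grid import EIGHT_CONNECTED, ElevationGrid, MarshMask

__all__ = [
    "Segment",
    "Outlet",
    "Channel",
    "CreekNetwork",
    "NetworkError",
    "build_network",
    "identify_outlets",
    "assign_reverse_strahler",
    "write_xyc",
]

Pixel = tuple[int, int]


class NetworkError(ValueError):
    """The skeleton cannot be turned into an ordered creek network."""


@dataclass
class Segment:
    """A maximal skeleton chain between two nodes (junctions/endpoints)."""

    id: int
    pixel_path: list  # ordered pixels, consecutive pixels are 8-neighbours
    length: float  # sinuous length (m), diagonal steps count sqrt(2)
    order: int | None = None
    channel_id: int | None = None
    parent_id: int | None = None


@dataclass
class Outlet:
    node: Pixel
    area: float  # mouth cross-sectional area (m^2)
    depth: float  # mouth depth (m)
    width: float  # mouth width (m)
    component: int


@dataclass
class Channel:
    """A merged chain of same-order segments, downstream end first."""

    id: int
    order: int
    component: int
    segment_ids: list
    pixel_path: list  # root (downstream) to far endpoint (upstream)
    length: float
    parent_id: int | None  # channel it branches off (None for order 1)
    junction: Pixel | None  # node where it meets its parent


@dataclass
class CreekNetwork:
    graph: nx.MultiGraph
    segments: dict
    node_type: dict  # pixel -> "endpoint" | "junction" | "outlet"
    cell_size: float
    outlets: list = field(default_factory=list)
    channels: dict = field(default_factory=dict)
    node_component: dict = field(default_factory=dict)
    removed_segments: list = field(default_factory=list)
    pruned_segments: list = field(default_factory=list)
    unordered_components: list = field(default_factory=list)
    isolated_pixels: list = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def endpoints(self) -> list:
        return sorted(p for p, t in self.node_type.items()
                      if t in ("endpoint", "outlet"))

    def order_counts(self) -> dict:
        counts: dict[int, int] = {}
        for ch in self.channels.values():
            counts[ch.order] = counts.get(ch.order, 0) + 1
        return counts


def _step_len(a: Pixel, b: Pixel) -> float:
    return float(np.hypot(a[0] - b[0], a[1] - b[1]))


def _path_length(path, cell_size: float) -> float:
    return sum(_step_len(a, b) for a, b in zip(path, path[1:])) * cell_size


def build_network(skel: SkeletonGrid, cell_size: float = 1.0) -> CreekNetwork:
    """Trace a skeleton into nodes and maximal chain segments.

    Every skeleton pixel belongs to at least one segment or is a node;
    isolated single pixels are recorded separately. Pure pixel cycles with
    no endpoint/junction get an arbitrary (smallest row, column) anchor node
    carrying a self-loop segment.
    """
    values = skel.values
    deg = _degree_map(values)
    graph = nx.MultiGraph()
    segments: dict[int, Segment] = {}
    node_type: dict[Pixel, str] = {}
    isolated: list[Pixel] = []

    if not values.any():
        warnings.warn("empty skeleton: network has no segments", stacklevel=2)
        return CreekNetwork(graph=graph, segments=segments,
                            node_type=node_type, cell_size=cell_size)

    node_px = sorted(zip(*np.nonzero(values & (deg != 2))))
    node_px = [(int(r), int(c)) for r, c in node_px]
    for p in node_px:
        if deg[p] == 0:
            isolated.append(p)
            node_type[p] = "endpoint"
            graph.add_node(p)
        else:
            node_type[p] = "endpoint" if deg[p] == 1 else "junction"
            graph.add_node(p)
    node_set = set(node_px)

    def neighbours(p: Pixel):
        r, c = p
        for dr, dc in _NEIGHBOR_CYCLE:
            rr, cc = r + dr, c + dc
            if 0 <= rr < values.shape[0] and 0 <= cc < values.shape[1] \
                    and values[rr, cc]:
                yield (rr, cc)

    next_id = 0
    used: set[tuple[Pixel, Pixel]] = set()  # directed first steps
    visited_mid: set[Pixel] = set()

    def add_segment(path):
        nonlocal next_id
        seg = Segment(id=next_id, pixel_path=path,
                      length=_path_length(path, cell_size))
        segments[next_id] = seg
        graph.add_edge(path[0], path[-1], key=next_id, length=seg.length)
        next_id += 1

    for n in node_px:
        if deg[n] == 0:
            continue
        for nb in sorted(neighbours(n)):
            if (n, nb) in used:
                continue
            used.add((n, nb))
            path = [n, nb]
            prev, cur = n, nb
            while cur not in node_set:
                visited_mid.add(cur)
                nxts = [q for q in neighbours(cur) if q != prev]
                # deg-2 pixel: exactly one way forward
                nxt = nxts[0]
                path.append(nxt)
                prev, cur = cur, nxt
            used.add((cur, prev))
            add_segment(path)

    # pure cycles: deg-2 pixels never visited
    remaining = sorted(set(zip(*np.nonzero(values & (deg == 2))))
                       - visited_mid - node_set)
    remaining = [(int(r), int(c)) for r, c in remaining]
    while remaining:
        s = remaining[0]
        node_type[s] = "junction"
        node_set.add(s)
        graph.add_node(s)
        first = sorted(neighbours(s))[0]
        path = [s, first]
        prev, cur = s, first
        while cur != s:
            visited_mid.add(cur)
            nxt = [q for q in neighbours(cur) if q != prev][0]
            path.append(nxt)
            prev, cur = cur, nxt
        add_segment(path)
        remaining = sorted(set(remaining) - visited_mid - {s})

    net = CreekNetwork(graph=graph, segments=segments, node_type=node_type,
                       cell_size=cell_size, isolated_pixels=isolated)
    for i, comp in enumerate(nx.connected_components(graph)):
        for node in comp:
            net.node_component[node] = i
    return net


def _marsh_boundary(marsh: MarshMask) -> np.ndarray:
    """Marsh cells on the grid edge or 8-adjacent to non-marsh cells."""
    interior = ndimage.binary_erosion(marsh.values, structure=EIGHT_CONNECTED,
                                      border_value=0)
    return marsh.values & ~interior


def identify_outlets(net: CreekNetwork, marsh: MarshMask, mask: CreekMask,
                     grid: ElevationGrid, fit_len: int = 5) -> CreekNetwork:
    """Type the outlet endpoints and rank them by mouth cross-section area.

    Mouth clusters are 8-connected groups of creek-mask pixels lying on the
    marsh boundary (grid edge, seawall breach or seaward limit); each
    cluster's outlet is the nearest skeleton endpoint. Mouth width, depth
    and area come from a transect near the outlet end of its segment.
    Outlets are sorted by area (largest first), ties by row then column.
    """
    from .morphometrics import cross_section

    boundary = _marsh_boundary(marsh)
    mouth = mask.values & boundary
    if not mouth.any():
        raise NetworkError("no creek-mask pixel touches the marsh boundary: "
                           "network cannot be ordered")
    endpoints = [p for p, t in sorted(net.node_type.items())
                 if t in ("endpoint", "outlet") and net.graph.degree(p) >= 1]
    if not endpoints:
        raise NetworkError("network has no endpoints to serve as outlets")
    ep_arr = np.array(endpoints)
    labels, n_clusters = ndimage.label(mouth, structure=EIGHT_CONNECTED)
    chosen: list[Pixel] = []
    for lab in range(1, n_clusters + 1):
        px = np.column_stack(np.nonzero(labels == lab))
        d2 = ((ep_arr[:, None, :] - px[None, :, :]) ** 2).sum(axis=2).min(axis=1)
        best = int(np.argmin(d2))  # argmin takes first -> (row, col) order
        node = endpoints[best]
        if node not in chosen:
            chosen.append(node)

    outlets = []
    for node in chosen:
        # the single segment incident to this endpoint
        nbr = next(iter(net.graph.adj[node]))
        seg_id = sorted(net.graph.adj[node][nbr])[0]
        seg = net.segments[seg_id]
        path = seg.pixel_path if seg.pixel_path[0] == node \
            else list(reversed(seg.pixel_path))
        station = min(fit_len, max(1, len(path) // 2))
        xs = cross_section(grid, mask, path, station, fit_len=fit_len)
        if xs is None:
            width = depth = area = 0.0
        else:
            width, depth, area = xs
        net.node_type[node] = "outlet"
        outlets.append(Outlet(node=node, area=area, depth=depth, width=width,
                              component=net.node_component[node]))
    outlets.sort(key=lambda o: (-o.area, o.node))
    net.outlets = outlets
    return net


def _break_cycles(net: CreekNetwork, H: nx.MultiGraph) -> None:
    """Remove the shortest segment of every cycle (reported on the net)."""
    # self-loops first
    for u, v, k in sorted(nx.selfloop_edges(H, keys=True),
                          key=lambda e: e[2]):
        if H.degree(u) == 2:  # pure cycle component
            raise NetworkError(f"pure cycle with no endpoint at {u}")
        H.remove_edge(u, v, key=k)
        net.removed_segments.append(k)
    # parallel edges are 2-cycles: keep the longest, drop the rest
    seen_pairs = set()
    for u, v in list(H.edges()):
        pair = tuple(sorted((u, v)))
        if pair in seen_pairs:
            continue
        seen_pairs.add(pair)
        keys = sorted(H[u][v])
        if len(keys) > 1:
            keys.sort(key=lambda k: (-H[u][v][k]["length"], k))
            for k in keys[1:]:
                H.remove_edge(u, v, key=k)
                net.removed_segments.append(k)
    # remaining simple cycles
    while True:
        cycles = nx.cycle_basis(nx.Graph(H))
        if not cycles:
            break
        cyc = cycles[0]
        edges = []
        for a, b in zip(cyc, cyc[1:] + cyc[:1]):
            k = sorted(H[a][b])[0]
            edges.append((H[a][b][k]["length"], k, a, b))
        edges.sort(key=lambda e: (e[0], e[1]))
        _, k, a, b = edges[0]
        H.remove_edge(a, b, key=k)
        net.removed_segments.append(k)


def _prune_graph_spurs(net: CreekNetwork, H: nx.MultiGraph, min_len: float,
                       protected: set) -> None:
    """Drop sub-threshold terminal stubs hanging off junctions.

    Cycle-breaking around thinned junction blobs can leave 1-2 px dangling
    segments; counted as channels they would inflate every per-order
    statistic. Outlet nodes are never pruned away."""
    changed = True
    while changed:
        changed = False
        for node in sorted(H.nodes()):
            if H.degree(node) != 1 or node in protected:
                continue
            nbr = next(iter(H.adj[node]))
            key = sorted(H.adj[node][nbr])[0]
            if H.adj[node][nbr][key]["length"] < min_len \
                    and H.degree(nbr) >= 3:
                H.remove_edge(node, nbr, key=key)
                H.remove_node(node)
                net.pruned_segments.append(key)
                changed = True


def assign_reverse_strahler(net: CreekNetwork,
                            seg_areas: dict | None = None,
                            spur_len: float = 0.0) -> CreekNetwork:
    """Order every segment by recursive longest-path pruning from outlets.

    Each connected component with at least one outlet is ordered from its
    largest outlet; its longest sinuous path becomes the order-1 (entry)
    channel, and every tributary branching off an order-k channel roots the
    order-(k+1) channel of its own subnetwork. Cycles are broken beforehand
    by removing the shortest segment in each cycle, and terminal stubs
    shorter than ``spur_len`` (m) left by that step are pruned. Components
    with no outlet are reported and excluded.
    """
    if seg_areas is None:
        seg_areas = {}
    H = net.graph.copy()
    _break_cycles(net, H)
    if spur_len > 0:
        _prune_graph_spurs(net, H, spur_len,
                           {o.node for o in net.outlets})
    for seg in net.segments.values():
        seg.order = seg.channel_id = seg.parent_id = None
    net.channels = {}
    net.unordered_components = []
    assigned: set[int] = set()
    next_channel = [0]
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 100_000))
    try:
        outlet_by_comp: dict[int, Outlet] = {}
        for o in net.outlets:  # already sorted largest-area first
            outlet_by_comp.setdefault(o.component, o)
        for comp_nodes in nx.connected_components(H):
            comp_id = net.node_component[sorted(comp_nodes)[0]]
            if len(comp_nodes) == 1 and H.degree(next(iter(comp_nodes))) == 0:
                continue
            root_outlet = outlet_by_comp.get(comp_id)
            if root_outlet is None:
                net.unordered_components.append(sorted(comp_nodes)[0])
                continue
            _assign_from(net, H, root_outlet.node, 1, None, assigned,
                         seg_areas, next_channel, comp_id)
    finally:
        sys.setrecursionlimit(old_limit)
    return net


def _best_path(H, node, came_key, assigned, seg_areas):
    """Longest available path from ``node``: (length, -mean_area, end, segs).

    Returns None if no unassigned edge leaves the node. Ties in length are
    broken by larger mean segment cross-sectional area, then by smaller
    (row, col) of the far endpoint.
    """
    best = None
    for nbr in sorted(H.adj[node]):
        for key in sorted(H.adj[node][nbr]):
            if key in assigned or key == came_key:
                continue
            seglen = H.adj[node][nbr][key]["length"]
            sub = _best_path(H, nbr, key, assigned, seg_areas)
            if sub is None:
                cand = (seglen, nbr, [key])
            else:
                cand = (seglen + sub[0], sub[1], [key] + sub[2])
            if best is None or _path_better(cand, best, seg_areas):
                best = cand
    return best


def _path_better(a, b, seg_areas) -> bool:
    if abs(a[0] - b[0]) > 1e-9:
        return a[0] > b[0]
    area_a = float(np.mean([seg_areas.get(k, 0.0) for k in a[2]]))
    area_b = float(np.mean([seg_areas.get(k, 0.0) for k in b[2]]))
    if abs(area_a - area_b) > 1e-12:
        return area_a > area_b
    return a[1] < b[1]


def _oriented(seg: Segment, start: Pixel) -> list:
    if seg.pixel_path[0] == start:
        return list(seg.pixel_path)
    assert seg.pixel_path[-1] == start
    return list(reversed(seg.pixel_path))


def _assign_from(net, H, root, order, parent_channel, assigned, seg_areas,
                 next_channel, comp_id):
    res = _best_path(H, root, None, assigned, seg_areas)
    if res is None:
        return
    _, _, seg_ids = res
    cid = next_channel[0]
    next_channel[0] += 1
    # stitch pixel path downstream -> upstream and link segment parents
    path: list[Pixel] = []
    nodes: list[Pixel] = [root]
    cur = root
    prev_seg = None
    for k in seg_ids:
        seg = net.segments[k]
        p = _oriented(seg, cur)
        path.extend(p if not path else p[1:])
        cur = p[-1]
        nodes.append(cur)
        seg.order = order
        seg.channel_id = cid
        seg.parent_id = prev_seg
        prev_seg = k
        assigned.add(k)
    parent = net.channels.get(parent_channel) if parent_channel is not None \
        else None
    ch = Channel(id=cid, order=order, component=comp_id, segment_ids=seg_ids,
                 pixel_path=path, length=_path_length(path, net.cell_size),
                 parent_id=parent_channel,
                 junction=root if parent is not None else None)
    net.channels[cid] = ch
    if parent is not None:
        # the channel's first segment drains into its parent channel's
        # segment at the junction
        for k in parent.segment_ids:
            ps = net.segments[k]
            if root in (ps.pixel_path[0], ps.pixel_path[-1]):
                net.segments[seg_ids[0]].parent_id = k
                break
    # tributaries branching off this channel, downstream to upstream
    for node in nodes:
        for nbr in sorted(H.adj[node]):
            for key in sorted(H.adj[node][nbr]):
                if key not in assigned:
                    _assign_from(net, H, node, order + 1, cid, assigned,
                                 seg_areas, next_channel, comp_id)
    return


def write_xyc(net: CreekNetwork, grid: ElevationGrid, path) -> None:
    """Export the ordered skeleton as "x y order" lines (XYC dialect).

    Junction pixels shared by channels of different orders take the lower
    (more downstream) order. Output is row-major, deterministic.
    """
    from pathlib import Path

    order_grid = np.zeros(grid.values.shape, dtype=int)
    for ch in sorted(net.channels.values(), key=lambda c: -c.order):
        for r, c in ch.pixel_path:
            order_grid[r, c] = ch.order
    rows, cols = np.nonzero(order_grid)
    lines = []
    for r, c in zip(rows, cols):
        x, y = grid.cell_center(int(r), int(c))
        lines.append(f"{x:.3f} {y:.3f} {order_grid[r, c]:d}")
    Path(path).write_text("\n".join(lines) + "\n")
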