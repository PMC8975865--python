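"""Shared fixtures: tiny grids, drawn skeletons and ordering helpers."""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pytest
from hypothesis import settings
from skimage.draw import line as _line

from creekmorph.detect import SkeletonGrid
from creekmorph.network import (CreekNetwork, Outlet, assign_reverse_strahler,
                                build_network)

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


def draw_skeleton(shape, segments) -> np.ndarray:
    """Rasterize ((r0, c0), (r1, c1)) line segments into a boolean grid."""
    out = np.zeros(shape, dtype=bool)
    for (r0, c0), (r1, c1) in segments:
        rr, cc = _line(r0, c0, r1, c1)
        out[rr, cc] = True
    return out


def ordered_network(skel_values: np.ndarray, outlet_pixels,
                    cell_size: float = 1.0) -> CreekNetwork:
    """Build a network and order it from fabricated outlets.

    ``outlet_pixels`` is a list of (pixel, area) pairs; each pixel snaps to
    the nearest endpoint node. Bypasses creek-mask outlet detection so
    ordering can be tested on bare skeletons.
    """
    net = build_network(SkeletonGrid(values=skel_values), cell_size=cell_size)
    endpoints = net.endpoints()
    outlets = []
    for px, area in outlet_pixels:
        node = min(endpoints,
                   key=lambda p: ((p[0] - px[0]) ** 2 + (p[1] - px[1]) ** 2, p))
        net.node_type[node] = "outlet"
        outlets.append(Outlet(node=node, area=area, depth=0.0, width=0.0,
                              component=net.node_component[node]))
    outlets.sort(key=lambda o: (-o.area, o.node))
    net.outlets = outlets
    return assign_reverse_strahler(net)


def order_at(net: CreekNetwork, pixel) -> int | None:
    """Reverse-Strahler order of the segment containing a pixel."""
    for seg in net.segments.values():
        if tuple(pixel) in seg.pixel_path:
            return seg.order
    raise AssertionError(f"pixel {pixel} not on any segment")


def oracle_orders(net: CreekNetwork, root) -> dict:
    """Independent longest-path pruning oracle on the segment graph.

    Recursive re-statement of the ordering rule (longest sinuous path from
    the root; tributaries branching off an order-k path root order-(k+1)
    subnetworks; length ties broken by smaller far endpoint), written
    without reference to the package's channel machinery. Returns
    {segment id: order}. Assumes an acyclic graph.
    """
    adj = defaultdict(list)
    for u, v, k, data in net.graph.edges(keys=True, data=True):
        adj[u].append((v, k, data["length"]))
        adj[v].append((u, k, data["length"]))

    def longest(node, banned):
        best = None
        for nbr, key, length in sorted(adj[node]):
            if key in banned:
                continue
            sub = longest(nbr, banned | {key})
            cand = (length + (sub[0] if sub else 0.0),
                    sub[1] if sub else nbr,
                    [key] + (sub[2] if sub else []),
                    [node] + (sub[3] if sub else [nbr]))
            if best is None or cand[0] > best[0] + 1e-9 or \
                    (abs(cand[0] - best[0]) <= 1e-9 and cand[1] < best[1]):
                best = cand
        return best

    orders: dict[int, int] = {}

    def assign(node, k):
        res = longest(node, set(orders))
        if res is None:
            return
        for key in res[2]:
            orders[key] = k
        for n in res[3]:
            for nbr, key, _ in sorted(adj[n]):
                if key not in orders:
                    assign(n, k + 1)

    assign(root, 1)
    return orders


# --- the constructed skeleton library -------------------------------------
# Each entry: shape, line segments, outlet (pixel, area) list, expected
# per-order channel counts (hand-traced from the pruning rule), and expected
# orders at representative pixels where hand-traced.

# All junctions are Y-joins whose three arms are pairwise >= 90 degrees
# apart: under 8-connectivity, tighter joins make a branch's first pixel
# touch interior stem pixels and manufacture junction blobs.

SKELETON_LIBRARY = {
    "line": dict(
        shape=(60, 60), segments=[((50, 10), (50, 40))],
        outlets=[((50, 10), 1.0)],
        counts={1: 1}, probes={(50, 25): 1},
    ),
    "zigzag": dict(
        # a bend is not a junction: one segment, order 1 throughout
        shape=(40, 40), segments=[((10, 10), (20, 20)), ((20, 20), (10, 30))],
        outlets=[((10, 10), 1.0)],
        counts={1: 1}, probes={(20, 20): 1, (15, 25): 1},
    ),
    "y_unequal": dict(
        # stem + long left branch (continues as order 1) + short right branch
        shape=(70, 70), segments=[((60, 30), (45, 30)), ((45, 30), (30, 15)),
                                  ((45, 30), (35, 40))],
        outlets=[((60, 30), 1.0)],
        counts={1: 1, 2: 1},
        probes={(55, 30): 1, (37, 22): 1, (40, 35): 2},
    ),
    "comb": dict(
        # zigzag main stem with 3 short teeth, every tooth shorter than the
        # remaining stem: stem is order 1 end to end, teeth are order 2
        shape=(70, 50),
        segments=[((60, 30), (52, 30)), ((52, 30), (46, 36)),
                  ((46, 36), (38, 36)), ((38, 36), (32, 42)),
                  ((52, 30), (48, 26)), ((46, 36), (50, 40)),
                  ((38, 36), (34, 32))],
        outlets=[((60, 30), 1.0)],
        counts={1: 1, 2: 3},
        probes={(56, 30): 1, (49, 33): 1, (42, 36): 1, (34, 40): 1,
                (50, 28): 2, (48, 38): 2, (36, 34): 2},
    ),
    "h_double_y": dict(
        # central bar with a Y at each end (H topology: 5 segments,
        # 2 junctions); upper legs tie -> the (24,24) leg joins order 1
        shape=(55, 55),
        segments=[((40, 30), (30, 30)),
                  ((40, 30), (46, 36)), ((40, 30), (46, 24)),
                  ((30, 30), (24, 36)), ((30, 30), (24, 24))],
        outlets=[((46, 24), 1.0)],
        counts={1: 1, 2: 2},
        probes={(43, 27): 1, (35, 30): 1, (27, 27): 1,
                (43, 33): 2, (27, 33): 2},
    ),
    "binary_depth2": dict(
        # equal diagonal children: tie broken towards smaller far endpoint
        shape=(70, 70), segments=[((60, 30), (45, 30)), ((45, 30), (35, 20)),
                                  ((45, 30), (35, 40))],
        outlets=[((60, 30), 1.0)],
        counts={1: 1, 2: 1},
        probes={(55, 30): 1, (40, 25): 1, (40, 35): 2},
    ),
    "binary_depth3": dict(
        shape=(70, 70),
        segments=[((60, 30), (50, 30)),
                  ((50, 30), (40, 20)), ((50, 30), (40, 40)),
                  ((40, 20), (32, 12)), ((40, 20), (32, 28)),
                  ((40, 40), (32, 32)), ((40, 40), (32, 48))],
        outlets=[((60, 30), 1.0)],
        # hand-trace: order 1 = stem + left child + left-left leaf (ties all
        # resolve towards the smaller far endpoint); the right subtree's
        # longest path is an order-2 channel of 2 segments; the two leaves
        # passed over become order 2 (left side) and order 3 (right side)
        counts={1: 1, 2: 2, 3: 1},
        probes={(55, 30): 1, (45, 25): 1, (36, 16): 1,
                (45, 35): 2, (36, 36): 2, (36, 24): 2, (36, 44): 3},
    ),
    "binary_depth4": dict(
        shape=(110, 130),
        segments=[((100, 64), (80, 64)),
                  ((80, 64), (56, 40)), ((80, 64), (56, 88)),
                  ((56, 40), (40, 40)), ((56, 40), (68, 28)),
                  ((56, 88), (40, 88)), ((56, 88), (68, 100)),
                  ((40, 40), (30, 30)), ((40, 40), (30, 50)),
                  ((68, 28), (76, 20)), ((68, 28), (76, 36)),
                  ((40, 88), (30, 78)), ((40, 88), (30, 98)),
                  ((68, 100), (76, 92)), ((68, 100), (76, 108))],
        outlets=[((100, 64), 1.0)],
        # perfect binary tree of depth 4: along any root-leaf main path the
        # side subtrees have depths 3, 2, 1, so channel counts per order are
        # shape-invariant: 1, 3, 3, 1
        counts={1: 1, 2: 3, 3: 3, 4: 1},
        probes={(90, 64): 1},
    ),
    "two_outlet": dict(
        # one component, two boundary endpoints; ordering starts only from
        # the larger outlet and the entry channel runs through to the far
        # (smaller) outlet, which is longer than the branch detour
        shape=(60, 60), segments=[((50, 10), (42, 18)), ((42, 18), (50, 26)),
                                  ((42, 18), (36, 18))],
        outlets=[((50, 10), 8.0), ((50, 26), 3.0)],
        counts={1: 1, 2: 1},
        probes={(46, 14): 1, (46, 22): 1, (39, 18): 2},
    ),
    "two_components": dict(
        # detached networks are ordered independently, each from its outlet
        shape=(60, 60),
        segments=[((50, 5), (44, 11)), ((44, 11), (36, 11)),
                  ((44, 11), (48, 15)),
                  ((50, 35), (44, 41)), ((44, 41), (34, 41)),
                  ((44, 41), (48, 45))],
        outlets=[((50, 5), 5.0), ((50, 35), 2.0)],
        counts={1: 2, 2: 2},
        probes={(40, 11): 1, (46, 13): 2, (38, 41): 1, (46, 43): 2},
    ),
    "cycle": dict(
        # a diamond ring hanging off the entry channel: the ring is the
        # cycle's only segment, so cycle-breaking removes it (reported) and
        # the remaining tail is the order-1 channel
        shape=(70, 70),
        segments=[((60, 30), (50, 30)), ((50, 30), (44, 24)),
                  ((44, 24), (38, 30)), ((38, 30), (44, 36)),
                  ((44, 36), (50, 30))],
        outlets=[((60, 30), 1.0)],
        counts={1: 1},
        probes={(55, 30): 1},
        n_removed=1,
    ),
}


@pytest.fixture(scope="session")
def small_marsh():
    """One shared noise-free synthetic marsh plus its extraction result."""
    from creekmorph.pipeline import extract
    from creekmorph.synthetic import (MarshSpec, default_tides, generate_marsh,
                                      suggested_config)

    spec = MarshSpec(noise_sigma=0.0, seed=4)
    grid, marsh, truth = generate_marsh(spec)
    res = extract(grid, marsh, suggested_config(spec), tides=default_tides())
    return spec, grid, marsh, truth, res
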