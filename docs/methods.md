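# Methods

## Scope and data model

`creekmorph` maps and parametrises tidal creek networks from a gridded
elevation model. Grids follow the Esri ASCII convention: row 0 is the
northern-most row, `(x, y)` of a cell means its centre, and the origin is
the lower-left corner (centre-origin headers are normalised on read).
Missing data are NaN in memory and a sentinel (default −9999) on disk.
Elevations are metres on an ODN-like vertical datum; the working
horizontal resolution is 1 m, the scale at which ~1 m-wide creeks remain
resolvable while sensitivity re-runs stay cheap.

## Preprocessing

* **Mosaic merge** — same-resolution tiles are stamped in order, last tile
  winning on overlap (the overlap rule is a package choice; co-registration
  is required).
* **Aggregation** — block mean of non-missing cells, anchored at the
  north-west corner; fully missing blocks stay missing. The
  count-weighted mean is conserved to 1e-9 relative.
* **Gap filling** — pure nearest-neighbour assignment by Euclidean
  distance, ties broken by smallest row then column. Nearest-neighbour
  (rather than any averaging interpolator) is deliberate: it preserves the
  sharp elevation step at channel edges that detection relies on.
* **Marsh cropping** — cells below the local HAT, optionally intersected
  with a boundary polygon, keeping the largest 8-connected region (the
  scheme's catchment).
* **Slope** — the Horn 3×3 operator in degrees (the standard GIS "slope"
  kernel), reflected padding at edges, missing propagating to any window
  that contains it. The operator is invariant to a constant elevation
  offset and commutes with transposition.

## Detection and repair

A creek is a connected low-lying feature with steep edges. Candidates are
in-marsh cells with `z <= z_t` **or** slope `>= s_t`; an 8-connected
candidate component is kept only if it contains at least one
elevation-qualified cell, which discards slope-only features such as
seawall toes. Components below `n_min` pixels are noise. Remaining
fragments are reconnected to the growing trunk along the straight
(Bresenham) segment between the closest pixel pair, nearest fragment
first, capped at `d_max` metres; fragments beyond reach are reported, not
silently dropped. Repair only ever adds pixels.

`z_t` can be given absolutely or relative to a tidal level (e.g.
MHWN − 0.5 m). The four thresholds are site-specific user inputs; the
synthetic generator's `suggested_config` places `z_t` halfway between the
platform and the shallowest carved bed and `s_t` at 75°, above the
seawall-toe slope of its surfaces, so detection is elevation-driven there.

## Skeleton and network

Thinning uses Zhang-style skeletonisation followed by a deterministic
cleanup that deletes redundant pixels of any remaining 2×2 block — simple
points (crossing number 1) first, then, around junction blobs where no
block pixel is locally simple, a pixel whose removal keeps the global
8-connected component count (this may open a micro-loop but never splits
a creek). Terminal spurs shorter than `prune_px` (default 5 px,
approximately one channel width) are pruned: thinning retracts blunt
channel ends into short forks that would otherwise count as channels.

The skeleton becomes a multigraph: nodes are pixels with one neighbour
(endpoints) or three or more (junctions); edges are maximal chains, with
sinuous length counting diagonal steps as √2 cells. Outlets are the
endpoints nearest to each 8-connected cluster of creek-mask pixels on the
marsh boundary (grid edge or cells adjacent to non-marsh), ranked by
mouth cross-sectional area measured a few pixels inside the mouth.

**Reverse-Strahler ordering** makes the entry channel order 1 — the
reverse of headwater-first Strahler ordering, which suits networks that
grow inland from a breach. Per component: cycles are broken by removing
the shortest segment of each cycle (reported); stubs left by that step
are pruned; then the longest sinuous path from the largest outlet is the
order-1 channel, and recursively every tributary branching off an order-k
channel roots the order-(k+1) channel of its hanging subtree. Ties in
path length break by larger mean segment cross-sectional area, then by
smaller (row, column) of the far endpoint, making ordering fully
deterministic. Components without an outlet are excluded and reported.
"Channel" means one such merged path; per-segment orders are inherited.

## Morphometrics

* **Transects** sample half-cell strips outward from the centreline,
  perpendicular to the chord fitted over ±5 pixels. Width is the in-mask
  strip extent; the bank level is the mean elevation of the two first
  out-of-mask cells; depth is bank minus minimum bed; area integrates
  max(0, bank − z) over the strips — exact for cell-wise constant
  profiles (a w×d rectangle yields exactly w·d). Transects that leave the
  grid or hit missing data are flagged and skipped. Stations sit every 5
  pixels, excluding 5 pixels at channel ends.
* **Junction angle** — angle between the tributary's first-5-pixel chord
  and the parent's downstream chord through the junction; 90° is a
  perpendicular join, near-180° a tributary doubling back upstream.
* **Whole-network parameters** — TCL sums ordered channel lengths; DD =
  (TCL km)/(marsh km²); OPL is the mean of the Euclidean
  distance-transform over in-marsh non-creek cells (creek cells would
  only dilute the mean with zeros); MCL is the order-1 channel of the
  largest-outlet component; NB counts merged channels; CSA sums mouth
  areas; PA is creek-mask area; SR is the length-weighted mean channel
  sinuosity; MCG = arctan((z_head − z_mouth)/MCL), positive when the head
  is higher. TP (creek volume / undermarsh tidal prism) uses a local
  bank-top reference: each creek pixel's bank is the elevation of its
  nearest non-creek marsh cell, avoiding any dependence on a tidal datum.
* **Per-order tables** — counts, total/mean length, bifurcation ratio
  N(k+1)/N(k) (≥1 for tree-like networks under reverse ordering), mean
  sinuosity, junction angle, width, depth, area, A/D = area/depth² and
  W/D = width/depth.
* **Sensitivity** — the pipeline is re-run at `z_t + {−δ, 0, +δ}` with δ
  defaulting to 0.15 m, the lidar vertical resolution; per parameter the
  sample standard deviation (n−1, as only three runs contribute) and its
  percentage of the mean are reported. Bitwise-identical runs report
  exactly 0. Runs yielding an empty network are excluded and listed.
* **Elevation change** — Δz between co-registered epochs; accreting cells
  bin by distance to the most recent creek extent, eroding cells by
  distance to the initial extent, 1 m bins to 20 m (beyond which site
  elevation and multiple-creek effects confound attribution).

## Synthetic marshes

The generator emulates exactly the structure the detector assumes: a flat
platform (default 2 m) ringed by a seawall (top 6 m), breached where each
creek tree's entry channel crosses the south wall; dendritic binary trees
carved with per-order widths (5/4/3 m), depths (1.2/1.0/0.8 m) and
segment lengths (220/60/22 m on the 300 m default extent), rectangular or
parabolic cross-sections, optional sinusoidal meandering; Gaussian
vertical noise (default σ = 0.15 m, the lidar vertical resolution; tests
use ≤ 0.05 m where a tolerance presumes clean separation) and nodata
speckle, both applied after ground truth is recorded. Tributaries attach
in the first part of their parent and the generator verifies that every
parent out-reaches its child subtrees, so construction orders coincide
with reverse-Strahler orders; violating specs are rejected rather than
silently producing mismatched truth. Default tidal levels (HAT 4.9 …
MLWS −0.5 m ODN) bracket the platform.

The generator does **not** emulate standing water in creek beds,
vegetation bias, gradual banks, or real lidar acquisition artefacts:
passing recovery tests bounds algorithmic error on clean dendritic
geometry, not sensor error on real marshes — where widths tend to be
over- and depths under-estimated when creeks hold water.

## Numerical choices and limitations

* 8-connectivity throughout (diagonally touching creek pixels are one
  creek); all tie-breaks are lexicographic (row, then column) and
  documented where they occur, so identical inputs give byte-identical
  outputs, including CSVs.
* Length comparisons in ordering use a 1e-9 m tolerance; distances in
  repair and gap filling compare integer squared pixel distances, so
  tie-breaking is exact.
* Problem sizes: the test suite and the acceptance script use 300 m
  synthetic marshes (90 000 cells), a size at which every stage is
  exercised and the whole suite runs in seconds; the pipeline itself is
  linear-ish in cell count and handles 500 m grids equally well.
* Known limitations: reconnection bridges are straight lines, not
  least-cost paths; thinning can displace the centreline by ~half a cell,
  which bounds sinuosity at ≈1.002 even for perfectly straight channels
  and adds small jogs at junctions; very short channels (< 2·fit_len
  pixels) have no valid transect stations and report missing width/depth;
  ordering of a component is undefined (and reported) when no outlet
  touches the marsh boundary.
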