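# creekmorph

Semi-automated extraction and morphometric parametrisation of tidal creek
networks from gridded elevation data, built for monitoring coastal-wetland
restoration (managed realignment) schemes and natural saltmarshes.

Creek networks are the plumbing of a saltmarsh: they set how the tide
floods and drains the platform, and their growth after a seawall is
breached is one of the clearest signals that a restored site is maturing.
Mapping them by hand from lidar is slow and subjective; flow-accumulation
channel extraction struggles on engineered sites whose creeks do not
follow a natural drainage gradient. `creekmorph` instead detects creeks by
a *threshold* definition — a connected feature lying lower than the
surrounding marsh, with edges delimited by steeper slopes — and converts
the detected mask into an ordered channel network with a full parameter
suite.

## Method

For a DEM `z` (1 m cells, ODN-like datum) cropped to the marsh below the
local Highest Astronomical Tide (HAT):

1. **Detection** — creek candidates are in-marsh cells with `z <= z_t` or
   Horn slope `>= s_t`; 8-connected components with no low cell (seawall
   toes) are dropped.
2. **Repair** — components smaller than `n_min` pixels are removed as
   noise; detached channel fragments within `d_max` of the trunk are
   reconnected along straight Bresenham bridges, nearest first.
3. **Skeletonisation** — topology-preserving thinning to a one-pixel
   centreline; sub-threshold terminal spurs are pruned.
4. **Reverse-Strahler ordering** — the *entry* channel is order 1: per
   component, the longest sinuous path from the largest outlet (by mouth
   cross-sectional area) is the order-1 channel; each tributary branching
   off an order-k channel roots the order-(k+1) channel of its own
   subnetwork, recursively.
5. **Morphometrics** — per channel: sinuous/straight length, sinuosity
   S = L_sinuous / L_straight >= 1, junction angle, and transect width,
   depth and cross-sectional area; per network: drainage density
   DD = TCL / A (km/km²), overmarsh path length OPL (mean Euclidean
   distance to the nearest creek), main channel length MCL, total channel
   length TCL, number of creeks NB, total mouth cross-sectional area CSA,
   mouth depth D, planform area PA, creek volume TP, network sinuosity SR
   and main channel gradient MCG.

Detection uncertainty is quantified by re-running with `z_t ± 0.15` m (the
vertical resolution of airborne lidar) and reporting the per-parameter
standard deviation. A two-epoch mode attributes elevation gains to
proximity to the most recent creek extent and losses to the initial
extent, binned out to 20 m.

Mean tidal levels (HAT, MHWS, MHWN, MWS, MLWN, MLWS) for a site are
interpolated from a port table by inverse-distance weighting within 30 km,
after Chart Datum → ODN conversion.

A first-class synthetic-marsh generator (`creekmorph.synthetic`) carves
dendritic creek trees of known geometry into a noisy platform, so every
stage is testable against ground truth without any external data.

## Worked example

```sh
python examples/01_extract_network.py
```

prints, for a seeded 300 m × 300 m synthetic marsh with a depth-3 creek
tree and 0.05 m vertical noise:

```
channels per reverse-Strahler order: {1: 1, 2: 2, 3: 4} (ground truth {1: 1, 2: 2, 3: 4})
total channel length TCL =    419.6 m   (truth 428.0)
drainage density     DD  =    4.853 km/km2 (truth 4.951)
overmarsh path length OPL =    64.2 m
main channel length  MCL =    220.1 m
number of creeks     NB  =        7
network sinuosity    SR  =    1.019
creek volume         TP  =     1947 m3
```

The pipeline recovers the carved per-order channel counts exactly and TCL
and DD within 2%; OPL says an average marsh cell sits ~64 m from the
nearest creek. The other examples cover tidal-level interpolation,
threshold sensitivity and the two-epoch elevation-change analysis.

## Command line

```sh
creekmorph generate --out site --size 300 --depth 3 --noise 0.05 --seed 1
creekmorph run --config site/config.json --out site/results
```

`run` writes, per epoch, the marsh XYZ, creek XYZ, ordered-skeleton XYC
("x y order" lines), per-channel and per-order CSVs and the network CSV,
plus optional sensitivity and change-analysis tables. Identical configs
give byte-identical bundles.

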