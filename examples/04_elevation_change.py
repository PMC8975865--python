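"""Attribute elevation change between two epochs to creek proximity.

Epoch 0 is the fresh synthetic marsh; epoch 1 adds accretion concentrated
within 5 m of the creeks. Positive changes are binned by distance to the
recent creek extent, negative changes by distance to the initial extent.
"""

import numpy as np
from scipy import ndimage

from creekmorph import extract
from creekmorph.grid import ElevationGrid
from creekmorph.morphometrics import elevation_change_vs_distance
from creekmorph.synthetic import MarshSpec, generate_marsh, suggested_config

spec = MarshSpec(noise_sigma=0.0, seed=3)
grid0, marsh, truth = generate_marsh(spec)
res0 = extract(grid0, marsh, suggested_config(spec))

dist = ndimage.distance_transform_edt(~res0.mask_repaired.values)
accretion = np.where(dist <= 5.0, 0.08, 0.01)
grid1 = ElevationGrid(values=grid0.values + accretion, cell_size=1.0)
res1 = extract(grid1, marsh, suggested_config(spec))

table = elevation_change_vs_distance(grid0, grid1, marsh,
                                     res0.mask_repaired, res1.mask_repaired)
pos = table[(table["sign"] == "positive") & (table["n"] > 0)]
print(pos.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# Mean dz steps from ~0.08 m in the bins inside 5 m of the creeks down to
# ~0.01 m beyond: the deposition signal tracks creek proximity.
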