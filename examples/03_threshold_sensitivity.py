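"""Quantify detection uncertainty from the elevation threshold.

Re-runs the pipeline with the creek elevation threshold shifted by the
lidar vertical resolution (+/- 0.15 m) and reports, per morphometric
parameter, the spread across the three runs.
"""

from creekmorph.morphometrics import threshold_sensitivity
from creekmorph.synthetic import (MarshSpec, default_tides, generate_marsh,
                                  suggested_config)

spec = MarshSpec(noise_sigma=0.05, seed=2)
grid, marsh, _ = generate_marsh(spec)
table = threshold_sensitivity(grid, marsh, suggested_config(spec),
                              tides=default_tides())
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# A std of 0 means the detected mask is insensitive to the threshold at
# that vertical scale; large percentages flag parameters whose values
# should be quoted with this processing uncertainty attached.
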