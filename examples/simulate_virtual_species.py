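"""Build a virtual species and sample decade-stamped, center-biased records.

The generator is the test bed for the whole pipeline: the species'
suitability surface is known exactly, so any downstream estimate can be
compared against truth.
"""

import numpy as np

import decade_enm as de

land = de.generate_landscape((0, 0, 1, 1), 100, 100, n_layers=4, seed=1)
truth = de.define_virtual_species(land, np.array([2.0, -1.5, 1.0, -0.5]), 0.0)
centers = de.place_research_centers((0, 0, 1, 1), n_centers=5, seed=2)

plan = de.SamplingPlan(bias_strength=2.0, seed=3)  # default 8-period plan
occ = de.sample_occurrences(truth, centers, plan)

print(f"true presence fraction: {truth.presence_mask.mean():.3f}")
print(f"sampled records: {len(occ)} over years {occ.year.min()}–{occ.year.max()}")
d = de.nearest_center_distance(occ, centers)
print(f"mean distance to nearest research center: {d.mean():.3f} map units")
# The presence fraction is the share of the landscape truly suitable;
# the distance summary reflects the exp(-2 * distance) collection bias.
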