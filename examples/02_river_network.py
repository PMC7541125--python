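"""Derive the river network from the terrain.

D8 routing sends every cell to its steepest-descent neighbour; flow
accumulation counts upslope cells; Strahler order approximates stream
size, which the friction model turns into crossing penalties (canoe for
medium rivers, ferry for large ones).
"""

import numpy as np

from chw_access import LandscapeSpec, build_river_grid, generate

land = generate(LandscapeSpec(seed=7))
rivers = build_river_grid(land.dem, stream_threshold=50)

order = np.asarray(rivers.strahler.values)
acc = np.asarray(rivers.accumulation.values)
print(f"stream cells (accumulation >= 50): {(order > 0).sum()}")
print(f"highest Strahler order: {order.max()}")
for cls, name in ((1, "small"), (2, "medium (canoe)"), (3, "large (ferry)")):
    n = int((np.asarray(rivers.width_class.values) == cls).sum())
    print(f"  {name:>15} river cells: {n}")
print(f"largest catchment drains {acc.max()} of {acc.size} cells")
# Medium/large cells add 15/60 min of waiting time wherever a walking
# route crosses them.
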