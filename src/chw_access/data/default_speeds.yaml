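# Default walking-speed table for the friction surface.
#
# Baseline 5 km/h on bare ground and all road types; other land-cover
# classes reduce it.  These class speeds and the river-crossing delays are
# configuration, not measured ground truth: field programs should replace
# them with locally validated values.
#
# class_speeds maps land-cover integer class -> km/h; null = impassable
# (open water off the river network).

base_speed_kmh: 5.0
road_speed_kmh: 5.0
apply_slope_to_roads: true

class_labels:
  1: bare
  2: cropland
  3: shrub
  4: dense_forest
  5: water

class_speeds:
  1: 5.0
  2: 4.0
  3: 3.5
  4: 2.5
  5: null

# Waiting delay in minutes when crossing a river cell:
#   medium (20-60 m wide): dugout canoe; large (>60 m): ferry.
# Small streams incur no delay.
crossing_delay_min:
  medium: 15.0
  large: 60.0
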