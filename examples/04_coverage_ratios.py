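"""Population and surface-area coverage expected of each worker.

Fokontany population (zonal sum of the gridded population) and planar
area are split evenly among the fokontany's workers; ratios are compared
against inclusive thresholds of 1,000 people and 25 km2 per worker.
"""

from chw_access import (
    LandscapeSpec,
    coverage_summary,
    coverage_table,
    generate,
    polygon_areas,
    zonal_population,
)

land = generate(LandscapeSpec(seed=7))
pops, residual = zonal_population(land.population, land.fokontany)
cov = coverage_table(pops, polygon_areas(land.fokontany), land.roster)
s = coverage_summary(cov)

print(f"{s['n_with_acs']} fokontany, {s['total_acs']} workers, "
      f"{s['total_population']:,.0f} people (residual outside polygons: {residual:.1f})")
print(f"population per worker <= 1,000 in {s['prop_below_pop']:.0%} of fokontany")
print(f"area per worker <= 25 km2 in {s['prop_below_area']:.0%} of fokontany")
print(f"both thresholds met in {s['prop_below_both']:.0%}")
print(f"largest fokontany: {s['max_area_km2']:.1f} km2")
# Fokontany above either threshold flag places where the standard
# two-worker complement may be stretched thin.
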