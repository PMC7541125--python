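"""Generate a synthetic study area and look at what it contains.

The generator emulates the input stack of a rural accessibility study:
terrain, clustered population, land cover, roads, fokontany polygons,
facilities and a worker roster — all deterministic under the seed.
"""

from chw_access import LandscapeSpec, generate

spec = LandscapeSpec(seed=7)
land = generate(spec)

print(f"grid: {land.dem.shape} cells at {land.dem.cell_size:.0f} m")
print(f"total population: {land.population.values.sum():,.0f}")
print(f"fokontany: {len(land.fokontany)}, facilities:")
print(land.facilities.groupby("kind").size().to_string())
share2 = (land.roster["n_acs"] == 2).mean()
print(f"fokontany with exactly 2 community health workers: {share2:.0%}")
# ~92% of fokontany carry the standard complement of 2 workers; the rest
# mimic local adjustments (1 up to 6 workers).
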