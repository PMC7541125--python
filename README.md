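# chw-access

Geographic accessibility modelling for community health worker (CHW)
programs. In many rural health systems — the motivating setting is
Madagascar's *agents communautaires* — volunteer CHWs serve a *fokontany*
(the lowest administrative unit) and must walk to a supervising health
center (CSB) for supervision and resupply, and to a supply point (PA) for
commodities. Program managers need to know whether the demands placed on
these volunteers are realistic: how many people and how much terrain each
worker covers, and how long the walk to their facility actually is.

`chw-access` implements that analysis as a reusable pipeline on raster and
vector data in a projected metre CRS:

- **Coverage ratios** — zonal population and planar area per fokontany,
  split evenly among its workers, classified against inclusive thresholds
  (default 1,000 people and 25 km² per worker).
- **Friction surface** — minutes to cross each grid cell, from a baseline
  walking speed of 5 km/h on bare ground and roads, reduced per land-cover
  class, modulated by slope through Tobler's hiking function
  `W(s) = 6·exp(−3.5·|s + 0.05|)` km/h applied as the flat-normalised
  factor `W(s)/W(0)`, plus river-crossing delays (dugout canoe for medium
  rivers, ferry for large ones).
- **Hydrology** — the river network is derived from the DEM by D8
  steepest-descent routing and flow accumulation, with Strahler stream
  order standing in for river width.
- **Travel time** — least accumulated cost over the 8-connected grid, with
  the move i→j costing `½(f_i + f_j)·d` (`d` = 1 cardinal, √2 diagonal).
  Fokontany travel time is the unweighted mean over *habitable* cells
  (population density ≥ 10 persons/km²), since each habitable cell is an
  equally likely worker location.
- **Reassignment scenarios** — travel time to the assigned facility versus
  the closest eligible one, binned into ≤2 h / 2–4 h / >4 h, summarised per
  district.
- **Synthetic landscapes** — a seeded generator producing a fully
  self-consistent input stack (terrain, population, land cover, roads,
  fokontany, facilities, roster), so the whole pipeline is testable and
  demonstrable without proprietary data.

## Worked example

```python
from chw_access import LandscapeSpec, generate, run_pipeline

land = generate(LandscapeSpec(seed=7))   # 200×200 cells at 100 m
result = run_pipeline(land)
print(result.report)
```

On this landscape (40 fokontany, 82 workers, ~54,000 people) the pipeline
prints, among other things:

```
40 fokontany, 82 workers, 54,271 people
population per worker <= 1,000 in 88% of fokontany
area per worker <= 25 km2 in 100% of fokontany
both thresholds met in 88%
```

and for travel to health centers (hours, 1-way, dry season, on foot; from
`examples/05_reassignment_scenarios.py`, seed 7): mean travel time to the
*assigned* CSB exceeds the mean to the *closest* CSB, and the >4 h share
never worsens under reassignment — reassigning a fokontany to its closest
facility can only shorten its trip. The `examples/` scripts walk through
each capability (simulation, river network, friction and travel time,
coverage, scenarios) and print one annotated result each.

A thin CLI mirrors the pipeline stages:

```sh
chw-access simulate stack/ --seed 7      # write a synthetic input stack
chw-access report stack/ results/        # full pipeline: CSVs + report.md
```

(`hydrology`, `friction`, `traveltime`, `coverage` and `reassign` run the
individual stages.)

## Limitations

Dry-season, one-way pedestrian travel only; isotropic slope cost; class
walking speeds and crossing delays are configuration defaults, not field
measurements (see `docs/methods.md`).
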