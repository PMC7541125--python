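# Methods

This note documents the models implemented in `chw-access`, the defaults
they ship with, and the choices made where the design was genuinely open.

## Problem and data model

The pipeline estimates two things for volunteer community health workers
(CHWs) who each serve one fokontany: (i) the population and surface area
each worker is expected to cover, and (ii) the one-way pedestrian travel
time from their fokontany to the health center (CSB) and supply point (PA)
they are attached to, compared with the closest such facility.

All rasters share one north-up grid in a projected metre CRS (default cell
100 m). Cell (0,0) is the north-west corner; a value describes the whole
cell; point-in-cell tests use cell centers. Heterogeneous inputs (e.g. a
30 m DEM or a 300 m land-cover product) are resampled onto the reference
grid first — nearest-neighbour for categorical layers, bilinear for
continuous ones. The analysis CRS is a configuration string: areas in km²
and speeds in km/h require planar metres, so geographic (degree) inputs
are rejected rather than silently mishandled. GeoTIFF I/O is a minimal
tagged subset written with `tifffile` (pixel scale, tiepoint, nodata);
vector data is GeoJSON via `shapely`.

## Friction surface

Each cell gets the time in minutes to traverse it on foot:

1. **Land cover / roads.** Walking speed is 5 km/h on bare ground and all
   roads, reduced per class. The shipped defaults (cropland 4.0, shrub
   3.5, dense forest 2.5 km/h, open water impassable) are *configuration*,
   not measurements — field programs should substitute locally validated
   values in the YAML speed table. Roads override the land-cover speed;
   polylines are rasterized by the "center within half a cell" rule so the
   burned road stays 8-connected on the cost graph.
2. **Slope.** Tobler's hiking function `W(s) = 6·exp(−3.5·|s+0.05|)` km/h
   is applied as the multiplicative factor `W(s)/W(0)` so that flat-ground
   class speeds are preserved exactly and the 5 km/h baseline is not
   double-counted. Slope is the central-difference gradient magnitude
   (one-sided at borders); direction is deliberately collapsed — the
   accumulated cost surface is isotropic, matching the standard
   cost-distance tool family, so uphill and downhill crossings of a cell
   cost the same.
3. **Rivers.** The network comes from the DEM: depressions are filled by a
   priority-flood sweep with an epsilon ramp (deterministic N,NE,E,…
   neighbour order), guaranteeing every interior cell a strictly lower
   neighbour; D8 steepest-descent directions (drop weighted by distance,
   diagonals √2 further, so a cardinal neighbour wins raw-drop ties) feed
   topological flow accumulation; cells at or above the stream threshold
   (default 50 cells, configurable — there is no "correct" value without
   hydrographic data) are streams. Strahler order proxies width through a
   configurable map (orders ≤3 small, 4–5 medium, ≥6 large). Medium
   river cells add a 15 min canoe delay, large ones a 60 min ferry delay —
   defaults chosen to be plausible waiting times and explicitly visible in
   config, since no measured values exist. Small streams cost nothing
   extra. Open water *off* the stream network is impassable; on-network
   water is crossed (base speed + delay) rather than walked around, and a
   road over water acts as a causeway/bridge.

## Travel time

Facilities are snapped to the cell containing their coordinates, or to the
nearest passable cell within 3 cells (deterministic tie-break), else an
error. Accumulated cost from the source cells (cost 0 at the source — a
convention, stated rather than inherited) is an exact shortest path on the
8-connected graph with move cost `½(f_i+f_j)·d`; the implementation builds
that graph explicitly and solves it with Dijkstra
(`scipy.sparse.csgraph`); tests verify it against an independent
pure-Python Dijkstra and against `skimage.graph.MCP_Geometric`, which
implements the same move convention.

A fokontany's travel time to a facility is the *unweighted* mean of the
field over habitable cells (density ≥ 10 persons/km²) whose centers lie in
the polygon — every habitable cell is an equally likely worker location,
so population weighting is deliberately absent. If a fokontany has no
habitable cell the mean falls back to all its cells and the record is
flagged. "Closest facility" defaults to the argmin of these fokontany
means over eligible facilities (workers of a fokontany are reassigned as a
unit; ties break by facility id); a per-cell-minimum variant
(`closest_method="cell_min"`) is available for comparison and is never
slower than the argmin. CSBs with no workers assigned anywhere are not
eligible reassignment targets; fokontany whose commune lacks a PA are
excluded from the PA analysis with an explicit reason. Only dry-season
parameters exist; the `season` argument is a hook.

## Coverage

Fokontany population is the zonal sum of the population raster over cell
centers; a center exactly on a shared boundary goes to the first covering
polygon so partitions conserve the total. Area is planar shapely area in
the analysis CRS. Population and area are split evenly among a
fokontany's workers (the heterogeneous-split problem is out of scope), and
thresholds are inclusive: ≤1,000 people and ≤25 km² per worker. Zero-worker
fokontany are kept with flagged undefined ratios.

## Synthetic landscapes

The generator emulates the *structure* of the real input stack, not any
real geography. Defaults describe a 20×20 km rural area at 100 m
resolution: smoothed Gaussian terrain (relief ~300 m, correlation length
1.5 km) over a trend tilted to the south-west corner with unequal x/y
coefficients (no two 8-neighbours are level), internally filled so D8
drains to the border; 40 settlements drawn low-elevation-biased with
lognormal populations (median 1,100, σ=0.7 — most fokontany around one to
two thousand people, a heavy right tail) spread by Gaussian kernels of
300–800 m; land cover from quantiles of a smooth field blended with
elevation; roads as the minimum spanning tree over settlements; fokontany
as Voronoi cells of settlement centers, grouped into 8 communes around
seeded seats and two districts split at the median seat easting. Worker
counts follow a distribution with 92% of fokontany at exactly 2 workers
(range 1–6); ~15% of settlements host a CSB and each commune seat hosts a
PA with probability 0.85, so a small share of fokontany is excluded from
the PA analysis, exercising that bookkeeping.

Facility assignment is the generator's one structural simplification: with
misassignment probability `p` (default 0.30) a fokontany is assigned a
uniformly chosen non-nearest CSB, otherwise its *straight-line* nearest.
Computing travel-time-nearest inside the generator would couple it to the
friction model it exists to test; Euclidean proximity keeps the generator
independent, at the cost that the realised share of "not assigned to the
travel-time-closest facility" exceeds `p` in rough terrain. The assigned
PA is always the commune's PA, mirroring how supply points follow
administrative rather than catchment boundaries.

What passing tests on these landscapes shows: the algorithms are exact
against oracles, directionally correct (reassignment never worsens travel
time), deterministic, and conserve what they should. What it does not
show: that the default speeds, delays or thresholds describe any real
district — headline percentages computed here are properties of the
synthetic defaults, not estimates for a real program.

## Numerical choices

- Depression filling uses ε = 1e-4 m steps; flats resolve toward the
  outlet they were flooded from.
- Friction on a flat bare 100 m cell at 5 km/h is exactly 1.2 min; all
  oracle comparisons use absolute tolerance 1e-9 (float summation order).
- Travel-time bins are [0,120], (120,240], (240,∞) minutes — exactly 120
  min counts as "within 2 hours". Reports round hours to 2 decimals and
  percentages to whole numbers.
- Problem sizes: the default landscape is 200×200 cells; test landscapes
  are 50–60 cells square so the full suite and the acceptance script run
  in seconds.

## Known limitations

No CRS reprojection (inputs must arrive in one projected metre CRS); no
Shapefile I/O (GeoJSON only); single-direction (D8) routing without
multi-flow dispersion; isotropic slope cost; dry season only; no
mechanized or bicycle travel; no optimal facility placement — scenarios
only evaluate reassignment to existing facilities.
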