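"""Seeded synthetic study area for end-to-end testing of the pipeline.

Emulates the input stack of a rural accessibility study: a smooth DEM with
drainage to the border, a clustered population surface (Gaussian settlement
kernels biased to low ground), a categorical land-cover layer, roads as a
minimum spanning tree over settlements, Voronoi fokontany polygons grouped
into communes and two districts, facilities (health centers at a subset of
settlements, supply points at commune seats) and a worker roster of ~2
workers per fokontany with a tunable share of fokontany assigned to a
facility that is not their nearest.

Everything is deterministic under the spec seed: the same
:class:`LandscapeSpec` always produces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from shapely.geometry import LineString, MultiPoint, Point, box
from shapely.ops import voronoi_diagram

from .geodata import (
    DEFAULT_CRS,
    Grid,
    VectorLayer,
    make_grid,
    write_geojson,
    write_grid,
)
from .hydrology import fill_depressions

__all__ = ["LandscapeSpec", "Landscape", "make_dem", "make_population",
           "make_landcover", "make_roads", "make_admin_and_roster",
           "generate", "write_landscape", "load_landscape"]

# land-cover integer codes shared with the default speed table
LC_BARE, LC_CROP, LC_SHRUB, LC_FOREST, LC_WATER = 1, 2, 3, 4, 5


@dataclass
class LandscapeSpec:
    """Parameters of the synthetic study area.

    Defaults sketch a 20×20 km rural district pair at 100 m resolution:
    40 settlements (hence 40 fokontany), ~92% of fokontany with exactly two
    workers, ~15% of settlements hosting a health center, supply points at
    most commune seats, and a 30% chance that a fokontany's assigned health
    center is not its nearest.
    """

    shape: tuple[int, int] = (200, 200)
    cell_size: float = 100.0
    seed: int = 0
    n_settlements: int = 40
    n_communes: int = 8
    # terrain
    relief_amplitude_m: float = 300.0
    correlation_length_cells: float = 15.0
    trend_relief_m: float = 150.0
    # population
    settlement_pop_median: float = 1100.0
    settlement_pop_sigma: float = 0.7
    settlement_spread_m: tuple[float, float] = (300.0, 800.0)
    # land cover class -> mixture weight (quantile shares of a smooth field)
    landcover_weights: dict[int, float] = field(
        default_factory=lambda: {LC_BARE: 0.15, LC_CROP: 0.35, LC_SHRUB: 0.30, LC_FOREST: 0.20}
    )
    # facilities and roster
    csb_fraction: float = 0.15
    pa_commune_prob: float = 0.85
    acs_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.02, 2: 0.92, 3: 0.04, 4: 0.01, 5: 0.005, 6: 0.005}
    )
    misassignment_prob: float = 0.30
    crs_id: str = DEFAULT_CRS

    def __post_init__(self) -> None:
        if self.n_settlements > 0 and self.n_settlements < max(
            1, round(self.csb_fraction * self.n_settlements)
        ):
            raise ValueError("more facilities requested than settlements")
        if self.n_communes > self.n_settlements:
            raise ValueError("more communes than settlements")
        if abs(sum(self.acs_distribution.values()) - 1.0) > 1e-9:
            raise ValueError("acs_distribution weights must sum to 1")
        if abs(sum(self.landcover_weights.values()) - 1.0) > 1e-9:
            raise ValueError("landcover_weights must sum to 1")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic substream per component."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class Landscape:
    """The full generated input stack, aligned on one grid."""

    spec: LandscapeSpec
    dem: Grid
    population: Grid
    landcover: Grid
    roads: VectorLayer
    fokontany: VectorLayer
    roster: pd.DataFrame
    facilities: pd.DataFrame

    @property
    def district_map(self) -> dict[str, str]:
        return {
            str(a["fokontany_id"]): str(a["district"]) for _, a in self.fokontany.features
        }

    @property
    def commune_map(self) -> dict[str, str]:
        return {
            str(a["fokontany_id"]): str(a["commune_id"]) for _, a in self.fokontany.features
        }


# ---------------------------------------------------------------------------
# terrain
# ---------------------------------------------------------------------------

def make_dem(spec: LandscapeSpec) -> Grid:
    """Smoothed seeded noise over a sloping trend, depression-filled.

    The trend tilts toward the south-west corner with unequal x/y
    coefficients, so no two 8-neighbours are level and drainage off the
    border is well defined; the internal fill guarantees every interior
    cell a strictly descending D8 path to the border.
    """
    rows, cols = spec.shape
    yn, xn = np.mgrid[0:rows, 0:cols]
    trend = spec.trend_relief_m * (0.6 * xn / max(cols - 1, 1) + 0.4 * (rows - 1 - yn) / max(rows - 1, 1))
    z = trend.astype(float)
    if spec.relief_amplitude_m > 0:
        noise = spec.rng(0).standard_normal(spec.shape)
        noise = gaussian_filter(noise, sigma=spec.correlation_length_cells, mode="reflect")
        sd = noise.std()
        if sd > 0:
            noise *= spec.relief_amplitude_m / (4.0 * sd)  # ±2σ spans the amplitude
        z = z + noise
        grid = make_grid(z, spec.cell_size, crs_id=spec.crs_id)
        return fill_depressions(grid, epsilon=1e-4)
    return make_grid(z, spec.cell_size, crs_id=spec.crs_id)


# ---------------------------------------------------------------------------
# settlements and population
# ---------------------------------------------------------------------------

def _settlements(spec: LandscapeSpec, dem: Grid) -> pd.DataFrame:
    """Settlement centers (cells), populations and kernel spreads.

    Centers are drawn from candidate cells weighted toward low elevation,
    thinned to a minimum separation so Voronoi fokontany stay usable.
    Deterministic given the spec.
    """
    rng = spec.rng(1)
    rows, cols = spec.shape
    z = np.asarray(dem.values, dtype=float)
    margin = max(2, int(0.04 * min(rows, cols)))
    rr, cc = np.mgrid[margin:rows - margin, margin:cols - margin]
    rr, cc = rr.ravel(), cc.ravel()
    zsub = z[rr, cc]
    w = (zsub.max() - zsub + 1e-9) ** 2
    w /= w.sum()
    order = rng.choice(rr.size, size=min(rr.size, spec.n_settlements * 30), replace=False, p=w)
    min_sep = max(3.0, 0.6 * min(rows, cols) / np.sqrt(spec.n_settlements))
    chosen: list[int] = []
    for k in order:
        if len(chosen) == spec.n_settlements:
            break
        if all(np.hypot(rr[k] - rr[j], cc[k] - cc[j]) >= min_sep for j in chosen):
            chosen.append(k)
    if len(chosen) < spec.n_settlements:  # dense spec: relax separation
        for k in order:
            if len(chosen) == spec.n_settlements:
                break
            if k not in chosen:
                chosen.append(k)
    rows_c = rr[np.array(chosen, dtype=int)]
    cols_c = cc[np.array(chosen, dtype=int)]
    pops = rng.lognormal(np.log(spec.settlement_pop_median), spec.settlement_pop_sigma,
                         size=spec.n_settlements)
    lo, hi = spec.settlement_spread_m
    spreads = rng.uniform(lo, hi, size=spec.n_settlements)
    xy = np.array([dem.center_of(int(r), int(c)) for r, c in zip(rows_c, cols_c)])
    return pd.DataFrame(
        {
            "settlement": np.arange(spec.n_settlements),
            "row": rows_c,
            "col": cols_c,
            "x": xy[:, 0],
            "y": xy[:, 1],
            "population": pops,
            "spread_m": spreads,
        }
    )


def make_population(spec: LandscapeSpec, dem: Grid) -> Grid:
    """Sum of Gaussian settlement kernels, persons per cell.

    Each settlement contributes P·(A/2πσ²)·exp(−d²/2σ²) with A the cell
    area, so the grid total approximates the summed settlement populations
    when kernels sit inside the extent.  Zero settlements give a zero grid.
    """
    stt = _settlements(spec, dem) if spec.n_settlements > 0 else None
    pop = np.zeros(spec.shape, dtype=float)
    if stt is None or len(stt) == 0:
        return make_grid(pop, spec.cell_size, crs_id=spec.crs_id)
    cx, cy = dem.cell_centers()
    area = spec.cell_size ** 2
    for _, s in stt.iterrows():
        d2 = (cx - s["x"]) ** 2 + (cy - s["y"]) ** 2
        sigma2 = s["spread_m"] ** 2
        pop += s["population"] * area / (2 * np.pi * sigma2) * np.exp(-d2 / (2 * sigma2))
    return dem.with_values(pop, nodata=-1.0)


def make_landcover(spec: LandscapeSpec, dem: Grid) -> Grid:
    """Categorical land cover from quantiles of a smooth mixed field.

    The field blends seeded smoothed noise with normalised elevation so
    forest tends uphill; class shares follow the spec mixture weights in
    increasing class-code order (bare → forest → water if weighted).
    """
    rng = spec.rng(2)
    noise = gaussian_filter(rng.standard_normal(spec.shape), sigma=spec.correlation_length_cells / 2,
                            mode="reflect")
    z = np.asarray(dem.values, dtype=float)
    zn = (z - z.min()) / max(float(np.ptp(z)), 1e-9)
    fieldv = noise / max(noise.std(), 1e-9) + 1.2 * zn
    classes = sorted(spec.landcover_weights)
    weights = np.array([spec.landcover_weights[c] for c in classes])
    edges = np.quantile(fieldv, np.cumsum(weights)[:-1])
    lc = np.asarray(classes, dtype=np.int32)[np.searchsorted(edges, fieldv)]
    return dem.with_values(lc, nodata=0)


def make_roads(spec: LandscapeSpec, dem: Grid) -> VectorLayer:
    """Minimum spanning tree over settlement centers, straight polylines."""
    stt = _settlements(spec, dem)
    if len(stt) < 2:
        return VectorLayer([], spec.crs_id)
    xy = stt[["x", "y"]].to_numpy()
    dist = cdist(xy, xy)
    mst = minimum_spanning_tree(dist).tocoo()
    feats = []
    for k, (i, j) in enumerate(sorted(zip(mst.row.tolist(), mst.col.tolist()))):
        geom = LineString([tuple(xy[i]), tuple(xy[j])])
        feats.append((geom, {"road_id": f"r{k:03d}"}))
    return VectorLayer(feats, spec.crs_id)


# ---------------------------------------------------------------------------
# administrative units, facilities and roster
# ---------------------------------------------------------------------------

def make_admin_and_roster(
    spec: LandscapeSpec, population: Grid, dem: Grid
) -> tuple[VectorLayer, pd.DataFrame, pd.DataFrame]:
    """Voronoi fokontany, the worker roster and the facility table.

    Fokontany are Voronoi cells of settlement centers clipped to the grid
    extent, grouped into communes around seeded commune seats and split into
    two districts at the median commune-seat easting.  Health centers sit at
    the peak-population cell of selected settlements; each commune seat
    hosts a supply point with probability ``pa_commune_prob``.  With
    misassignment probability 0 every fokontany is assigned its nearest
    (straight-line) health center by construction.
    """
    stt = _settlements(spec, dem)
    rng = spec.rng(3)
    n = len(stt)
    xmin, ymin, xmax, ymax = population.bounds
    extent = box(xmin, ymin, xmax, ymax)
    pts = [Point(x, y) for x, y in zip(stt["x"], stt["y"])]
    cells = voronoi_diagram(MultiPoint(pts), envelope=extent)
    polys: list = [None] * n
    for cell in cells.geoms:
        clipped = cell.intersection(extent)
        for i, p in enumerate(pts):
            if polys[i] is None and cell.covers(p):
                polys[i] = clipped
                break
    if any(p is None or p.is_empty for p in polys):
        raise RuntimeError("Voronoi tessellation failed to cover all settlements")

    # communes: nearest of n_communes seeded seat settlements
    seat_idx = np.sort(rng.choice(n, size=spec.n_communes, replace=False))
    seats = stt.iloc[seat_idx]
    d_seat = cdist(stt[["x", "y"]], seats[["x", "y"]])
    commune_of = np.argmin(d_seat, axis=1)
    seat_x = seats["x"].to_numpy()
    east = seat_x >= np.median(seat_x)
    district_of_commune = np.where(east, "East", "West")

    # facilities
    n_csb = max(1, round(spec.csb_fraction * n))
    csb_idx = np.sort(rng.choice(n, size=n_csb, replace=False))
    fac_records = []
    csb_ids = {}
    for k, i in enumerate(csb_idx):
        fid = f"csb{k:02d}"
        csb_ids[int(i)] = fid
        fac_records.append({"facility_id": fid, "kind": "CSB",
                            "x": float(stt.at[i, "x"]), "y": float(stt.at[i, "y"]),
                            "eligible": True})
    pa_of_commune: dict[int, str | None] = {}
    k_pa = 0
    for ci in range(spec.n_communes):
        if rng.random() < spec.pa_commune_prob:
            fid = f"pa{k_pa:02d}"
            k_pa += 1
            i = int(seat_idx[ci])
            pa_of_commune[ci] = fid
            fac_records.append({"facility_id": fid, "kind": "PA",
                                "x": float(stt.at[i, "x"]), "y": float(stt.at[i, "y"]),
                                "eligible": True})
        else:
            pa_of_commune[ci] = None
    facilities = pd.DataFrame.from_records(fac_records)

    # roster
    counts = np.asarray(sorted(spec.acs_distribution), dtype=int)
    probs = np.array([spec.acs_distribution[int(c)] for c in counts])
    n_acs = rng.choice(counts, size=n, p=probs)
    csb_xy = stt.iloc[list(csb_ids)][["x", "y"]].to_numpy()
    csb_list = [csb_ids[i] for i in csb_ids]
    d_csb = cdist(stt[["x", "y"]], csb_xy)
    nearest = np.argmin(d_csb, axis=1)
    roster_records = []
    feats = []
    for i in range(n):
        fid = f"f{i:03d}"
        a = int(nearest[i])
        if len(csb_list) > 1 and rng.random() < spec.misassignment_prob:
            others = [k for k in range(len(csb_list)) if k != a]
            a = others[rng.integers(len(others))]
        ci = int(commune_of[i])
        roster_records.append(
            {
                "fokontany_id": fid,
                "n_acs": int(n_acs[i]),
                "assigned_csb_id": csb_list[a],
                "assigned_pa_id": pa_of_commune[ci],
            }
        )
        feats.append(
            (
                polys[i],
                {
                    "fokontany_id": fid,
                    "commune_id": f"c{ci:02d}",
                    "district": str(district_of_commune[ci]),
                    "settlement_x": float(stt.at[i, "x"]),
                    "settlement_y": float(stt.at[i, "y"]),
                },
            )
        )
    roster = pd.DataFrame.from_records(roster_records)
    assigned = set(roster["assigned_csb_id"])
    facilities["eligible"] = [
        (r["kind"] == "PA") or (r["facility_id"] in assigned)
        for _, r in facilities.iterrows()
    ]
    return VectorLayer(feats, spec.crs_id), roster, facilities


def generate(spec: LandscapeSpec) -> Landscape:
    """Build the complete self-consistent input stack for one spec."""
    dem = make_dem(spec)
    population = make_population(spec, dem)
    landcover = make_landcover(spec, dem)
    roads = make_roads(spec, dem)
    fokontany, roster, facilities = make_admin_and_roster(spec, population, dem)
    return Landscape(spec, dem, population, landcover, roads, fokontany, roster, facilities)


# ---------------------------------------------------------------------------
# on-disk layout
# ---------------------------------------------------------------------------

_FILES = {
    "dem": "dem.tif",
    "population": "population.tif",
    "landcover": "landcover.tif",
    "roads": "roads.geojson",
    "fokontany": "fokontany.geojson",
    "roster": "roster.csv",
    "facilities": "facilities.csv",
}


def write_landscape(landscape: Landscape, outdir: str | Path) -> None:
    """Write the stack with fixed names and deterministic formatting."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_grid(out / _FILES["dem"], landscape.dem)
    write_grid(out / _FILES["population"], landscape.population)
    write_grid(out / _FILES["landcover"], landscape.landcover)
    write_geojson(out / _FILES["roads"], landscape.roads)
    write_geojson(out / _FILES["fokontany"], landscape.fokontany)
    landscape.roster.to_csv(out / _FILES["roster"], index=False, lineterminator="\n")
    landscape.facilities.to_csv(out / _FILES["facilities"], index=False,
                                float_format="%.3f", lineterminator="\n")


def load_landscape(indir: str | Path, spec: LandscapeSpec | None = None) -> Landscape:
    """Read a stack written by :func:`write_landscape` (or hand-assembled)."""
    from .geodata import read_facilities, read_geojson, read_grid, read_roster

    d = Path(indir)
    dem = read_grid(d / _FILES["dem"])
    return Landscape(
        spec=spec or LandscapeSpec(shape=dem.shape, cell_size=dem.cell_size),
        dem=dem,
        population=read_grid(d / _FILES["population"]),
        landcover=read_grid(d / _FILES["landcover"]),
        roads=read_geojson(d / _FILES["roads"]),
        fokontany=read_geojson(d / _FILES["fokontany"]),
        roster=read_roster(d / _FILES["roster"]),
        facilities=read_facilities(d / _FILES["facilities"]),
    )
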