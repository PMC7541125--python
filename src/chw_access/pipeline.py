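"""End-to-end orchestration: input stack → friction → travel time →
coverage and reassignment scenarios → report.

The pipeline mirrors a field accessibility study: derive slope and the
river network from the DEM, burn roads onto the grid, assemble the friction
surface, accumulate least-cost travel time from every facility, then
summarise per-fokontany coverage ratios and assigned-versus-closest
travel-time scenarios for health centers (CSB) and supply points (PA).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .coverage import coverage_summary, coverage_table, polygon_areas, zonal_population
from .friction import SpeedTable, build_friction, slope_grid
from .geodata import Grid, VectorLayer, rasterize, write_grid
from .hydrology import RiverGrid, build_river_grid
from .scenarios import build_scenarios, district_summary, render_report
from .synthetic import Landscape
from .travel_time import facility_fields, habitable_mask, polygon_cell_indices

__all__ = ["PipelineResult", "run_pipeline", "write_outputs"]

_CSV_KW = dict(index=False, float_format="%.6f", lineterminator="\n")


@dataclass
class PipelineResult:
    friction: Grid
    rivers: RiverGrid
    mask: Grid
    fields: dict[str, Grid]
    mean_times: pd.DataFrame       # fokontany × facility mean minutes
    coverage: pd.DataFrame         # per-fokontany coverage records
    coverage_stats: dict
    scenarios: pd.DataFrame        # assigned vs closest, CSB and PA stacked
    summary: pd.DataFrame          # district travel-time statistics (hours)
    report: str
    residual_population: float


def run_pipeline(
    landscape: Landscape,
    speeds: SpeedTable | None = None,
    stream_threshold: int = 50,
    habitable_threshold_per_km2: float = 10.0,
    closest_method: str = "fokontany_mean",
    season: str = "dry",
) -> PipelineResult:
    """Run the full analysis on an aligned input stack.

    Only dry-season conditions are implemented; the ``season`` hook exists
    so a rainy-season parameter set can slot in without interface changes.
    """
    if season != "dry":
        raise NotImplementedError("only dry-season modelling is implemented")
    table = speeds or SpeedTable.from_yaml()
    dem, lc, pop = landscape.dem, landscape.landcover, landscape.population
    for g in (lc, pop):
        if not dem.same_geometry(g):
            raise ValueError("input grids are not aligned; run align_stack first")

    slope = slope_grid(dem)
    rivers = build_river_grid(dem, stream_threshold=stream_threshold)
    roads_grid = rasterize(landscape.roads, dem) if len(landscape.roads) else None
    friction = build_friction(lc, roads_grid, slope, rivers, table)
    mask = habitable_mask(pop, habitable_threshold_per_km2)

    fields, mean_times = facility_fields(friction, landscape.facilities, mask, landscape.fokontany)
    cell_idx = polygon_cell_indices(landscape.fokontany, pop)

    pops, residual = zonal_population(pop, landscape.fokontany, cell_indices=cell_idx)
    areas = polygon_areas(landscape.fokontany)
    cov = coverage_table(pops, areas, landscape.roster)
    cov_stats = coverage_summary(cov)

    scen_parts = []
    for kind in ("CSB", "PA"):
        scen_parts.append(
            build_scenarios(
                mean_times, landscape.roster, landscape.facilities, kind,
                method=closest_method, fields=fields, mask=mask, cell_indices=cell_idx,
            )
        )
    scenarios = pd.concat(scen_parts, ignore_index=True)
    summary = district_summary(scenarios, landscape.district_map)
    report = render_report(summary, scenarios, cov_stats)
    return PipelineResult(
        friction=friction,
        rivers=rivers,
        mask=mask,
        fields=fields,
        mean_times=mean_times,
        coverage=cov,
        coverage_stats=cov_stats,
        scenarios=scenarios,
        summary=summary,
        report=report,
        residual_population=residual,
    )


def write_outputs(result: PipelineResult, outdir: str | Path, write_rasters: bool = True) -> None:
    """Write CSV/report outputs (deterministic bytes) and key rasters."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.coverage.to_csv(out / "coverage.csv", **_CSV_KW)
    result.mean_times.to_csv(out / "travel_times.csv", **_CSV_KW)
    result.scenarios.to_csv(out / "scenarios.csv", **_CSV_KW)
    result.summary.to_csv(out / "summary.csv", **_CSV_KW)
    (out / "report.md").write_text(result.report + "\n")
    if write_rasters:
        write_grid(out / "friction.tif", result.friction)
        write_grid(out / "strahler.tif", result.rivers.strahler)
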