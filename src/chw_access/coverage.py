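"""Expected population and surface-area coverage per community health worker.

For each fokontany: zonal population from the gridded population surface,
planar polygon area in km², and per-worker ratios assuming population and
area are split evenly among the fokontany's workers.  Ratios are classified
against inclusive thresholds (default 1,000 people and 25 km² per worker,
"1,000 people or fewer" / "25 km² or less").
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geodata import Grid, VectorLayer
from .travel_time import polygon_cell_indices

__all__ = [
    "zonal_population",
    "polygon_areas",
    "coverage_table",
    "coverage_summary",
    "POP_THRESHOLD",
    "AREA_THRESHOLD_KM2",
]

POP_THRESHOLD = 1000.0
AREA_THRESHOLD_KM2 = 25.0

#: histogram bin edges for per-worker coverage distributions
POP_PER_AC_BINS = [0, 250, 500, 750, 1000, 1500, 2000, float("inf")]
AREA_PER_AC_BINS = [0, 5, 10, 25, 50, float("inf")]


def zonal_population(
    population: Grid,
    polygons: VectorLayer,
    id_field: str = "fokontany_id",
    cell_indices: dict[str, np.ndarray] | None = None,
) -> tuple[dict[str, float], float]:
    """Sum of cell population over cell centers inside each polygon.

    Returns (per-polygon totals, residual population whose cell centers fall
    outside every polygon).  With polygons partitioning the extent the
    residual is 0 and the totals conserve the grid sum.
    """
    pv = np.asarray(population.values, dtype=float).ravel()
    if cell_indices is None:
        cell_indices = polygon_cell_indices(polygons, population, id_field)
    sums = {pid: float(pv[cells].sum()) for pid, cells in cell_indices.items()}
    covered = np.zeros(pv.size, dtype=bool)
    for cells in cell_indices.values():
        covered[cells] = True
    residual = float(pv[~covered].sum())
    return sums, residual


def polygon_areas(polygons: VectorLayer, id_field: str = "fokontany_id") -> dict[str, float]:
    """Planar polygon area in km² in the analysis CRS."""
    return {
        str(attrs[id_field]): geom.area / 1e6 for geom, attrs in polygons.features
    }


def coverage_table(
    pop: dict[str, float],
    areas: dict[str, float],
    roster: pd.DataFrame,
    pop_threshold: float = POP_THRESHOLD,
    area_threshold_km2: float = AREA_THRESHOLD_KM2,
) -> pd.DataFrame:
    """Per-fokontany coverage record with even-split per-worker ratios.

    Rows with no worker at all get NaN ratios and ``undefined_ratios=True``
    rather than being dropped, so the bookkeeping stays complete.
    Threshold flags are inclusive (≤).
    """
    records = []
    for _, row in roster.iterrows():
        fid = str(row["fokontany_id"])
        if fid not in pop or fid not in areas:
            raise KeyError(f"fokontany {fid} missing population or area")
        n = int(row["n_acs"])
        p, a = pop[fid], areas[fid]
        if a <= 0:
            raise ValueError(f"fokontany {fid}: non-positive area")
        pop_per = p / n if n > 0 else float("nan")
        km2_per = a / n if n > 0 else float("nan")
        records.append(
            {
                "fokontany_id": fid,
                "population": p,
                "area_km2": a,
                "n_acs": n,
                "pop_per_ac": pop_per,
                "km2_per_ac": km2_per,
                "below_pop_threshold": bool(n > 0 and pop_per <= pop_threshold),
                "below_area_threshold": bool(n > 0 and km2_per <= area_threshold_km2),
                "undefined_ratios": n == 0,
            }
        )
    df = pd.DataFrame.from_records(records)
    df["below_both"] = df["below_pop_threshold"] & df["below_area_threshold"]
    return df


def coverage_summary(records: pd.DataFrame) -> dict:
    """Proportions below each threshold and per-worker histograms.

    Proportions are over fokontany with defined ratios (≥1 worker).
    """
    defined = records[~records["undefined_ratios"]]
    n = len(defined)
    if n == 0:
        raise ValueError("no fokontany with assigned workers")
    pop_hist = np.histogram(defined["pop_per_ac"], bins=POP_PER_AC_BINS)[0]
    area_hist = np.histogram(defined["km2_per_ac"], bins=AREA_PER_AC_BINS)[0]
    return {
        "n_fokontany": int(len(records)),
        "n_with_acs": n,
        "prop_below_pop": float(defined["below_pop_threshold"].mean()),
        "prop_below_area": float(defined["below_area_threshold"].mean()),
        "prop_below_both": float(defined["below_both"].mean()),
        "pop_per_ac_hist": pop_hist.tolist(),
        "area_per_ac_hist": area_hist.tolist(),
        "max_area_km2": float(records["area_km2"].max()),
        "total_population": float(records["population"].sum()),
        "total_acs": int(records["n_acs"].sum()),
    }
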