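"""Accumulated least-cost pedestrian travel time and fokontany summaries.

A facility is snapped to its grid cell and travel time to every other cell
is the least accumulated cost over the 8-connected grid graph, where a move
between adjacent cells i→j costs ½·(f_i + f_j)·d with f the per-cell
traversal friction in minutes and d = 1 (cardinal) or √2 (diagonal).  This
is the convention of the accumulated-cost-surface tools used for walking
accessibility analysis; source cells start at 0.

Because worker home locations are unknown, every habitable cell (population
density at or above a threshold, 10 persons/km² by default) is treated as
an equally likely worker location, and a fokontany's travel time is the
unweighted mean of the field over its habitable cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .geodata import Grid, VectorLayer
from .hydrology import NEIGHBOR_OFFSETS

__all__ = [
    "cost_distance",
    "habitable_mask",
    "snap_to_passable",
    "fokontany_mean_time",
    "polygon_cell_indices",
    "facility_fields",
]

_SQRT2 = math.sqrt(2.0)


def _grid_graph(friction: np.ndarray) -> csr_matrix:
    """Sparse 8-connected move-cost graph over passable cells.

    Impassable (+inf) cells keep their node index but have no incident
    edges.  Only the 4 forward offsets are emitted; the graph is used
    undirected, which matches the symmetric ½(f_i+f_j)·d move cost.
    """
    rows, cols = friction.shape
    n = rows * cols
    idx = np.arange(n).reshape(rows, cols)
    passable = np.isfinite(friction)
    src_list, dst_list, w_list = [], [], []
    for (dr, dc), dist in zip([(0, 1), (1, 0), (1, 1), (1, -1)], [1.0, 1.0, _SQRT2, _SQRT2]):
        sl_src = (slice(max(0, -dr), rows - max(0, dr)), slice(max(0, -dc), cols - max(0, dc)))
        sl_dst = (slice(max(0, dr), rows + min(0, dr)), slice(max(0, dc), cols + min(0, dc)))
        ok = passable[sl_src] & passable[sl_dst]
        src_list.append(idx[sl_src][ok])
        dst_list.append(idx[sl_dst][ok])
        w_list.append(0.5 * (friction[sl_src][ok] + friction[sl_dst][ok]) * dist)
    src = np.concatenate(src_list)
    dst = np.concatenate(dst_list)
    w = np.concatenate(w_list)
    return csr_matrix((w, (src, dst)), shape=(n, n))


def cost_distance(friction: Grid, sources: list[tuple[int, int]],
                  graph: csr_matrix | None = None) -> Grid:
    """Least accumulated minutes from the nearest source cell.

    ``sources`` are (row, col) cells; all-impassable sources raise.  Pass a
    prebuilt ``graph`` (from the same friction grid) to amortise graph
    construction across facilities.  Unreachable cells are +inf.
    """
    f = np.asarray(friction.values, dtype=float)
    rows, cols = f.shape
    src_idx = []
    for r, c in sources:
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"source cell {(r, c)} outside grid")
        if np.isfinite(f[r, c]):
            src_idx.append(r * cols + c)
    if not src_idx:
        raise ValueError("all source cells are impassable")
    if graph is None:
        graph = _grid_graph(f)
    d = dijkstra(graph, directed=False, indices=src_idx, min_only=len(src_idx) > 1)
    field = (d if d.ndim == 1 else d[0]).reshape(rows, cols)
    field[~np.isfinite(f)] = np.inf
    return friction.with_values(field, nodata=np.inf)


def habitable_mask(population: Grid, threshold_per_km2: float = 10.0) -> Grid:
    """Cells dense enough to potentially host a worker.

    Density is persons per cell divided by cell area in km²; the mask is
    density ≥ threshold (a 100 m cell holding one person is 100/km², well
    above the default 10/km²).
    """
    density = np.asarray(population.values, dtype=float) * (1e6 / population.cell_size**2)
    return population.with_values(density >= threshold_per_km2, nodata=False)


def snap_to_passable(friction: Grid, x: float, y: float, max_radius: int = 3) -> tuple[int, int]:
    """Cell of a facility point, moved to the nearest passable cell if needed.

    The search is limited to ``max_radius`` cells (Euclidean distance on
    centers, ties broken row-major); beyond that the facility is considered
    unplaceable and an error is raised.
    """
    r0, c0 = friction.index_of(x, y)
    f = np.asarray(friction.values, dtype=float)
    if np.isfinite(f[r0, c0]):
        return r0, c0
    rows, cols = f.shape
    best: tuple[float, int, int] | None = None
    for dr in range(-max_radius, max_radius + 1):
        for dc in range(-max_radius, max_radius + 1):
            r, c = r0 + dr, c0 + dc
            if 0 <= r < rows and 0 <= c < cols and np.isfinite(f[r, c]):
                d = math.hypot(dr, dc)
                if d <= max_radius and (best is None or (d, r, c) < best):
                    best = (d, r, c)
    if best is None:
        raise ValueError(
            f"facility at ({x}, {y}) has no passable cell within {max_radius} cells"
        )
    return best[1], best[2]


def polygon_cell_indices(polygons: VectorLayer, reference: Grid, id_field: str = "fokontany_id"
                         ) -> dict[str, np.ndarray]:
    """For each polygon, flattened indices of cells whose center lies inside.

    Computed once and reused across facilities and analyses so that zonal
    rules stay consistent pipeline-wide.  A center lying exactly on a shared
    polygon boundary goes to the first feature covering it (deterministic in
    layer order), so partitions stay partitions.
    """
    cx, cy = reference.cell_centers()
    half = reference.cell_size / 2.0
    taken = np.zeros(cx.size, dtype=bool)
    out: dict[str, np.ndarray] = {}
    for geom, attrs in polygons.features:
        pid = str(attrs[id_field])
        minx, miny, maxx, maxy = geom.bounds
        win = (cx >= minx - half) & (cx <= maxx + half) & (cy >= miny - half) & (cy <= maxy + half)
        rows, cols = np.nonzero(win)
        if rows.size == 0:
            out[pid] = np.empty(0, dtype=np.int64)
            continue
        inside = shapely.intersects_xy(geom, cx[rows, cols], cy[rows, cols])
        cells = rows[inside] * reference.shape[1] + cols[inside]
        cells = cells[~taken[cells]]
        taken[cells] = True
        out[pid] = cells
    return out


def fokontany_mean_time(
    field: Grid,
    mask: Grid,
    polygons: VectorLayer,
    facility_id: str = "",
    id_field: str = "fokontany_id",
    cell_indices: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Unweighted mean travel time over each polygon's habitable cells.

    Columns: fokontany_id, facility_id, mean_minutes, n_habitable_cells,
    used_fallback (no habitable cell — mean over all polygon cells instead),
    unreachable (no finite travel time at all).
    """
    fv = np.asarray(field.values, dtype=float).ravel()
    mv = np.asarray(mask.values, dtype=bool).ravel()
    if cell_indices is None:
        cell_indices = polygon_cell_indices(polygons, field, id_field)
    records = []
    for pid, cells in cell_indices.items():
        if cells.size == 0:
            raise ValueError(f"polygon {pid} contains no grid cell centers")
        hab = cells[mv[cells]]
        used_fallback = hab.size == 0
        use = cells if used_fallback else hab
        vals = fv[use]
        finite = np.isfinite(vals)
        unreachable = not finite.any()
        mean = float(np.mean(vals[finite])) if finite.any() else float("inf")
        records.append(
            {
                "fokontany_id": pid,
                "facility_id": facility_id,
                "mean_minutes": mean,
                "n_habitable_cells": int(hab.size),
                "used_fallback": used_fallback,
                "unreachable": unreachable,
            }
        )
    return pd.DataFrame.from_records(records)


def facility_fields(
    friction: Grid,
    facilities: pd.DataFrame,
    mask: Grid,
    polygons: VectorLayer,
    id_field: str = "fokontany_id",
) -> tuple[dict[str, Grid], pd.DataFrame]:
    """Cost-distance field per facility and the stacked fokontany means.

    Returns ({facility_id: field}, long DataFrame of fokontany × facility
    mean travel times).  The move-cost graph and polygon cell indices are
    built once and shared.
    """
    f = np.asarray(friction.values, dtype=float)
    graph = _grid_graph(f)
    cell_idx = polygon_cell_indices(polygons, friction, id_field)
    fields: dict[str, Grid] = {}
    tables = []
    for _, row in facilities.sort_values("facility_id").iterrows():
        rc = snap_to_passable(friction, float(row["x"]), float(row["y"]))
        fld = cost_distance(friction, [rc], graph=graph)
        fid = str(row["facility_id"])
        fields[fid] = fld
        tables.append(
            fokontany_mean_time(fld, mask, polygons, facility_id=fid,
                                id_field=id_field, cell_indices=cell_idx)
        )
    return fields, pd.concat(tables, ignore_index=True)
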