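"""River network derivation from a DEM: D8 routing, flow accumulation,
Strahler stream order and width classes.

The river network feeds crossing penalties into the friction surface: medium
rivers (20–60 m wide, crossed by dugout canoe) and large rivers (over 60 m,
crossed by ferry) add a waiting delay to the cells they occupy.  Since no
hydraulic width data exist, width is approximated from Strahler order
through a configurable order→class map.

Single-direction (D8) routing: every cell drains to its steepest-descent
neighbour of eight, with drop weighted by distance (diagonals √2 further),
so a cardinal neighbour wins a tie on raw drop.  The DEM must be
depression-filled first; :func:`fill_depressions` is a priority-flood fill
with an epsilon ramp so every interior cell keeps a strictly lower
neighbour and flats resolve deterministically toward their outlet.
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass

import numpy as np

from .geodata import Grid

__all__ = [
    "NEIGHBOR_OFFSETS",
    "OFF_GRID",
    "RiverGrid",
    "fill_depressions",
    "d8_flow_direction",
    "flow_accumulation",
    "strahler_order",
    "width_class",
    "build_river_grid",
    "DEFAULT_WIDTH_CLASS_MAP",
]

# D8 neighbour order N, NE, E, SE, S, SW, W, NW — also the deterministic
# tie-break order everywhere in this module.
NEIGHBOR_OFFSETS: list[tuple[int, int]] = [
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1),
]
_NEIGHBOR_DIST = np.array([1.0, np.sqrt(2), 1.0, np.sqrt(2)] * 2)

OFF_GRID = -1  # direction code for border cells draining off the grid

WIDTH_NONE, WIDTH_SMALL, WIDTH_MEDIUM, WIDTH_LARGE = 0, 1, 2, 3
WIDTH_LABELS = {WIDTH_NONE: "none", WIDTH_SMALL: "small", WIDTH_MEDIUM: "medium", WIDTH_LARGE: "large"}

#: order→class defaults: orders ≤3 small, 4–5 medium (canoe), ≥6 large (ferry)
DEFAULT_WIDTH_CLASS_MAP = {1: "small", 2: "small", 3: "small", 4: "medium", 5: "medium", 6: "large"}


@dataclass
class RiverGrid:
    """D8-derived river network on the analysis grid."""

    flow_direction: Grid   # int codes 0..7 (N..NW) or OFF_GRID
    accumulation: Grid     # upslope cell counts, each cell counts itself
    strahler: Grid         # stream order, 0 off-stream
    width_class: Grid      # 0 none, 1 small, 2 medium, 3 large


def fill_depressions(dem: Grid, epsilon: float = 1e-4) -> Grid:
    """Priority-flood depression filling.

    Floods inward from the border, raising each cell to at least the level of
    the cell it was reached from plus ``epsilon``.  With ``epsilon > 0`` every
    interior cell of the result has a strictly lower neighbour, so D8
    directions are defined everywhere and flats drain toward the outlet they
    were filled from (deterministic N,NE,E,… neighbour visiting order).
    With ``epsilon = 0`` this is the classical fill (flats stay flat).
    """
    z = np.asarray(dem.values, dtype=float).copy()
    rows, cols = z.shape
    filled = z.copy()
    visited = np.zeros_like(z, dtype=bool)
    heap: list[tuple[float, int, int, int]] = []
    counter = 0
    for r in range(rows):
        for c in range(cols):
            if r in (0, rows - 1) or c in (0, cols - 1):
                heapq.heappush(heap, (filled[r, c], counter, r, c))
                counter += 1
                visited[r, c] = True
    while heap:
        zv, _, r, c = heapq.heappop(heap)
        for dr, dc in NEIGHBOR_OFFSETS:
            nr, nc = r + dr, c + dc
            if 0 <= nr < rows and 0 <= nc < cols and not visited[nr, nc]:
                visited[nr, nc] = True
                filled[nr, nc] = max(filled[nr, nc], zv + epsilon)
                heapq.heappush(heap, (filled[nr, nc], counter, nr, nc))
                counter += 1
    return dem.with_values(filled)


def d8_flow_direction(dem: Grid) -> Grid:
    """Steepest-descent D8 directions on a depression-filled DEM.

    Each cell points to the in-grid neighbour maximising drop/distance
    (diagonal distance cell_size·√2).  Border cells with no descending
    in-grid neighbour drain off-grid (code ``OFF_GRID``).  An interior cell
    with no strictly lower neighbour means the DEM has an unresolved flat or
    pit; that is an error — fill/resolve first.
    """
    z = np.asarray(dem.values, dtype=float)
    rows, cols = z.shape
    # gradient toward each neighbour, -inf off-grid
    grads = np.full((8, rows, cols), -np.inf)
    for k, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        src = z[max(0, -dr):rows - max(0, dr), max(0, -dc):cols - max(0, dc)]
        dst = z[max(0, dr):rows + min(0, dr), max(0, dc):cols + min(0, dc)]
        drop = (src - dst) / (_NEIGHBOR_DIST[k] * dem.cell_size)
        grads[k, max(0, -dr):rows - max(0, dr), max(0, -dc):cols - max(0, dc)] = drop
    best = np.argmax(grads, axis=0)  # first max wins -> N,NE,E,... tie-break
    best_grad = np.take_along_axis(grads, best[None], axis=0)[0]
    direction = best.astype(np.int8)
    no_descent = best_grad <= 0
    border = np.zeros((rows, cols), dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    direction[no_descent & border] = OFF_GRID
    if np.any(no_descent & ~border):
        raise ValueError(
            "unresolved flat or pit in DEM interior; fill depressions "
            "(fill_depressions with epsilon > 0) before D8 routing"
        )
    return dem.with_values(direction, nodata=-128)


def _downstream_index(direction: np.ndarray) -> np.ndarray:
    """Flattened index of each cell's downstream cell; -1 drains off-grid."""
    rows, cols = direction.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    ds = np.full(direction.shape, -1, dtype=np.int64)
    for k, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        m = direction == k
        nr, nc = rr[m] + dr, cc[m] + dc
        if np.any((nr < 0) | (nr >= rows) | (nc < 0) | (nc >= cols)):
            raise ValueError("direction grid points off the raster from a non-border cell")
        ds[m] = nr * cols + nc
    return ds.ravel()


def flow_accumulation(direction: Grid) -> Grid:
    """Number of cells (each counting itself) draining through each cell.

    Kahn-style topological accumulation on the D8 forest; a cycle in the
    direction grid (corrupt input) raises.
    """
    dirv = np.asarray(direction.values)
    n = dirv.size
    ds = _downstream_index(dirv)
    indeg = np.bincount(ds[ds >= 0], minlength=n)
    acc = np.ones(n, dtype=np.int64)
    queue = deque(np.nonzero(indeg == 0)[0].tolist())
    processed = 0
    while queue:
        c = queue.popleft()
        processed += 1
        d = ds[c]
        if d >= 0:
            acc[d] += acc[c]
            indeg[d] -= 1
            if indeg[d] == 0:
                queue.append(d)
    if processed != n:
        raise ValueError("cycle detected in flow-direction grid (corrupt input)")
    return direction.with_values(acc.reshape(dirv.shape), nodata=0)


def strahler_order(direction: Grid, accumulation: Grid, stream_threshold: int = 50) -> Grid:
    """Strahler order of stream cells (accumulation ≥ threshold); 0 elsewhere.

    Head streams are order 1; at a junction the order is the maximum of the
    inflowing stream orders, plus one when that maximum is attained by two or
    more tributaries.
    """
    dirv = np.asarray(direction.values)
    accv = np.asarray(accumulation.values)
    n = dirv.size
    stream = (accv >= stream_threshold).ravel()
    ds = _downstream_index(dirv)
    indeg = np.bincount(ds[ds >= 0], minlength=n)
    order = np.zeros(n, dtype=np.int32)
    max_in = np.zeros(n, dtype=np.int32)    # max inflowing stream order
    n_at_max = np.zeros(n, dtype=np.int32)  # tributaries attaining it
    queue = deque(np.nonzero(indeg == 0)[0].tolist())
    while queue:
        c = queue.popleft()
        if stream[c]:
            if max_in[c] == 0:
                order[c] = 1
            else:
                order[c] = max_in[c] + (1 if n_at_max[c] >= 2 else 0)
        d = ds[c]
        if d >= 0:
            if stream[c] and order[c] > 0:
                if order[c] > max_in[d]:
                    max_in[d] = order[c]
                    n_at_max[d] = 1
                elif order[c] == max_in[d]:
                    n_at_max[d] += 1
            indeg[d] -= 1
            if indeg[d] == 0:
                queue.append(d)
    return direction.with_values(order.reshape(dirv.shape), nodata=0)


def width_class(strahler: Grid, class_map: dict[int, str] | None = None) -> Grid:
    """Map Strahler orders to width classes {none, small, medium, large}.

    Orders above the largest key in the map take the class of the largest
    key; order 0 (off-stream) is always 'none'.
    """
    cmap = DEFAULT_WIDTH_CLASS_MAP if class_map is None else class_map
    code = {"small": WIDTH_SMALL, "medium": WIDTH_MEDIUM, "large": WIDTH_LARGE}
    max_order = max(cmap)
    orders = np.asarray(strahler.values, dtype=np.int64)
    lut_len = max(int(orders.max()), max_order) + 1
    lut = np.zeros(lut_len, dtype=np.int8)
    for o in range(1, lut_len):
        cls = cmap.get(min(o, max_order))
        if cls is None:
            raise ValueError(f"width class map has no entry covering order {o}")
        lut[o] = code[cls]
    return strahler.with_values(lut[orders], nodata=WIDTH_NONE)


def build_river_grid(
    dem: Grid,
    stream_threshold: int = 50,
    class_map: dict[int, str] | None = None,
    fill: bool = True,
) -> RiverGrid:
    """DEM → full river network (fill → D8 → accumulation → order → width)."""
    filled = fill_depressions(dem) if fill else dem
    direction = d8_flow_direction(filled)
    acc = flow_accumulation(direction)
    order = strahler_order(direction, acc, stream_threshold)
    wc = width_class(order, class_map)
    return RiverGrid(direction, acc, order, wc)
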