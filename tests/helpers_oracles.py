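"""Independent brute-force oracles used by the test suite.

Each function here recomputes a quantity by the most direct method
available (explicit graph search, exhaustive walks, closed-form geometry)
and deliberately shares no code with the package implementation.
"""

import heapq
import math

import numpy as np

SQRT2 = math.sqrt(2.0)
OFFSETS8 = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def dijkstra_oracle(friction, sources):
    """Pure-Python heap Dijkstra on the explicit 8-connected move graph.

    Move cost i->j is (friction[i]+friction[j])/2 times 1 (cardinal) or
    sqrt(2) (diagonal); impassable cells (non-finite friction) have no
    edges.  Returns the full distance field (inf where unreachable).
    """
    f = np.asarray(friction, dtype=float)
    rows, cols = f.shape
    dist = np.full((rows, cols), np.inf)
    heap = []
    for r, c in sources:
        if np.isfinite(f[r, c]):
            dist[r, c] = 0.0
            heapq.heappush(heap, (0.0, r, c))
    while heap:
        d, r, c = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        for dr, dc in OFFSETS8:
            nr, nc = r + dr, c + dc
            if 0 <= nr < rows and 0 <= nc < cols and np.isfinite(f[nr, nc]):
                step = 0.5 * (f[r, c] + f[nr, nc]) * (SQRT2 if dr and dc else 1.0)
                nd = d + step
                if nd < dist[nr, nc]:
                    dist[nr, nc] = nd
                    heapq.heappush(heap, (nd, nr, nc))
    return dist


def walk_to_border(dem, r, c):
    """Follow strictly descending steepest-descent moves; True if the walk
    leaves the grid (i.e. reaches a border cell with no lower neighbour)."""
    z = np.asarray(dem, dtype=float)
    rows, cols = z.shape
    seen = set()
    while True:
        if (r, c) in seen:
            return False  # loop: trapped
        seen.add((r, c))
        best = None
        for dr, dc in OFFSETS8:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < rows and 0 <= nc < cols):
                continue
            drop = (z[r, c] - z[nr, nc]) / (SQRT2 if dr and dc else 1.0)
            if drop > 0 and (best is None or drop > best[0]):
                best = (drop, nr, nc)
        if best is None:
            return r in (0, rows - 1) or c in (0, cols - 1)
        r, c = best[1], best[2]


def accumulation_oracle(downstream, shape):
    """Count, for every cell, how many cells' flow paths pass through it,
    by walking each cell's full path to the outlet."""
    n = shape[0] * shape[1]
    acc = np.zeros(n, dtype=int)
    for start in range(n):
        c = start
        while c >= 0:
            acc[c] += 1
            c = downstream[c]
    return acc.reshape(shape)


def strahler_merge_oracle(depth):
    """Strahler order at the outlet of a perfect binary drainage tree."""
    def order(d):
        if d == 0:
            return 1
        o = order(d - 1)
        return o + 1  # two equal tributaries
    return order(depth)


def point_segment_distance(px, py, ax, ay, bx, by):
    vx, vy = bx - ax, by - ay
    wx, wy = px - ax, py - ay
    L2 = vx * vx + vy * vy
    t = 0.0 if L2 == 0 else max(0.0, min(1.0, (wx * vx + wy * vy) / L2))
    return math.hypot(px - (ax + t * vx), py - (ay + t * vy))


def point_in_polygon(px, py, ring):
    """Even-odd ray casting on an explicit exterior ring."""
    inside = False
    n = len(ring)
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside


def shoelace_area(ring):
    s = 0.0
    n = len(ring)
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % n]
        s += x1 * y2 - x2 * y1
    return abs(s) / 2.0


def binary_tree_directions(depth, n_extra_rows=1):
    """Embed a perfect binary drainage tree of the given depth in a D8
    direction grid (codes: index into OFFSETS8, -1 drains off-grid).

    Leaves sit in row 0; pairs of streams converge along SE/SW diagonals
    and merge, halving the stream count each round.  Returns (direction
    array, tree-cell mask, outlet cell).
    """
    SE, SW, S = 3, 5, 4
    n_leaves = 2 ** depth
    cols = 2 * n_leaves - 1
    rows = max(n_leaves, 2) + n_extra_rows
    d = np.full((rows, cols), -1, dtype=np.int8)
    tree = np.zeros((rows, cols), dtype=bool)
    active = list(range(0, 2 * n_leaves, 2))
    r = 0
    for c in active:
        tree[0, c] = True
    while len(active) > 1:
        nxt = []
        span = (active[1] - active[0]) // 2
        for c1, c2 in zip(active[0::2], active[1::2]):
            for i in range(span):
                d[r + i, c1 + i] = SE
                d[r + i, c2 - i] = SW
                tree[r + i, c1 + i] = tree[r + i, c2 - i] = True
            nxt.append((c1 + c2) // 2)
        r += span
        for c in nxt:
            tree[r, c] = True
        active = nxt
    for rr in range(r, rows - 1):
        d[rr, active[0]] = S
        tree[rr, active[0]] = True
    outlet = (rows - 1, active[0])
    tree[outlet] = True
    return d, tree, outlet
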