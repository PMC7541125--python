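"""D8 routing, flow accumulation, Strahler order and width classes."""

import numpy as np
import pytest
from skimage.morphology import reconstruction

from chw_access.geodata import make_grid
from chw_access.hydrology import (
    DEFAULT_WIDTH_CLASS_MAP,
    NEIGHBOR_OFFSETS,
    OFF_GRID,
    build_river_grid,
    d8_flow_direction,
    fill_depressions,
    flow_accumulation,
    strahler_order,
    width_class,
)
from helpers_oracles import (
    accumulation_oracle,
    binary_tree_directions,
    strahler_merge_oracle,
    walk_to_border,
)

CS = 100.0
N, NE, E, SE, S, SW, W, NW = range(8)


def _downstream(direction):
    rows, cols = direction.shape
    ds = np.full(rows * cols, -1, dtype=int)
    for r in range(rows):
        for c in range(cols):
            k = direction[r, c]
            if k >= 0:
                dr, dc = NEIGHBOR_OFFSETS[k]
                ds[r * cols + c] = (r + dr) * cols + (c + dc)
    return ds


class TestFillDepressions:
    def test_matches_morphological_reconstruction(self, rng):
        for _ in range(10):
            z = rng.standard_normal((12, 12)) * 10
            dem = make_grid(z, CS)
            filled = fill_depressions(dem, epsilon=0.0).values
            seed = z.copy()
            seed[1:-1, 1:-1] = z.max()
            expected = reconstruction(seed, z, method="erosion")
            np.testing.assert_allclose(filled, expected, atol=1e-9)

    def test_epsilon_fill_gives_strict_descent(self, rng):
        z = rng.standard_normal((15, 15)) * 5
        z[5:9, 5:9] -= 30  # a big pit
        filled = fill_depressions(make_grid(z, CS), epsilon=1e-4).values
        rows, cols = filled.shape
        for r in range(1, rows - 1):
            for c in range(1, cols - 1):
                drops = [filled[r, c] - filled[r + dr, c + dc] for dr, dc in NEIGHBOR_OFFSETS]
                assert max(drops) > 0

    def test_fill_never_lowers(self, rng):
        z = rng.standard_normal((10, 10))
        filled = fill_depressions(make_grid(z, CS), epsilon=1e-4).values
        assert (filled >= z - 1e-12).all()


class TestD8Direction:
    def test_plane_drains_west(self):
        dem = make_grid(np.tile(np.arange(8.0), (6, 1)) * 10, CS)
        d = d8_flow_direction(dem).values
        assert (d[:, 1:] == W).all()
        assert (d[:, 0] == OFF_GRID).all()

    def test_cardinal_beats_diagonal_on_equal_drop(self):
        # center cell has equal raw drop to N (cardinal) and NW (diagonal);
        # the sqrt(2) distance weighting must pick the cardinal neighbour
        z = np.array([[2.0, 2.0, 9.0], [9.0, 3.0, 9.0], [9.0, 9.0, 9.0]])
        d = d8_flow_direction(make_grid(z, CS)).values
        assert d[1, 1] == N

    def test_tilted_bowl_paths_reach_corner(self, rng):
        yy, xx = np.mgrid[0:10, 0:10].astype(float)
        z = 0.5 * xx + 0.3 * yy + 0.02 * ((xx - 5) ** 2 + (yy - 5) ** 2)
        dem = fill_depressions(make_grid(z, CS), epsilon=1e-4)
        for r in range(10):
            for c in range(10):
                assert walk_to_border(dem.values, r, c)

    def test_interior_flat_raises(self):
        z = np.ones((5, 5))
        z[0, 0] = 0.0
        with pytest.raises(ValueError, match="unresolved flat"):
            d8_flow_direction(make_grid(z, CS))


class TestFlowAccumulation:
    def test_plane_column_counts(self):
        dem = make_grid(np.tile(np.arange(7.0), (5, 1)), CS)
        acc = flow_accumulation(d8_flow_direction(dem)).values
        # draining west: column j counted from the east edge accumulates j+1
        for j in range(7):
            np.testing.assert_array_equal(acc[:, 6 - j], j + 1)

    def test_convergent_bowl_outlet_collects_everything(self):
        yy, xx = np.mgrid[0:9, 0:9].astype(float)
        z = np.hypot(xx - 0.3, yy - 0.2)  # tilted cone draining to one corner
        dem = fill_depressions(make_grid(z, CS), epsilon=1e-4)
        acc = flow_accumulation(d8_flow_direction(dem)).values
        assert acc[0, 0] == 81

    def test_matches_path_walk_oracle_on_random_dems(self, rng):
        for _ in range(8):
            z = rng.standard_normal((13, 13)) * 8
            dem = fill_depressions(make_grid(z, CS), epsilon=1e-4)
            direction = d8_flow_direction(dem)
            acc = flow_accumulation(direction).values
            ds = _downstream(np.asarray(direction.values))
            np.testing.assert_array_equal(acc, accumulation_oracle(ds, z.shape))

    def test_local_conservation_identity(self, rng):
        # acc(c) == 1 + sum of inflowing neighbours' accumulations
        z = rng.standard_normal((15, 15)) * 8
        dem = fill_depressions(make_grid(z, CS), epsilon=1e-4)
        direction = d8_flow_direction(dem)
        acc = flow_accumulation(direction).values.ravel()
        ds = _downstream(np.asarray(direction.values))
        inflow = np.zeros_like(acc)
        for c, d in enumerate(ds):
            if d >= 0:
                inflow[d] += acc[c]
        np.testing.assert_array_equal(acc, inflow + 1)

    def test_outlet_total_equals_cell_count(self, rng):
        z = rng.standard_normal((10, 10)) * 8
        dem = fill_depressions(make_grid(z, CS), epsilon=1e-4)
        direction = d8_flow_direction(dem)
        acc = flow_accumulation(direction).values.ravel()
        ds = _downstream(np.asarray(direction.values))
        outlets = acc[ds == -1]
        assert outlets.sum() == 100

    def test_cycle_raises(self):
        d = np.full((3, 3), OFF_GRID, dtype=np.int8)
        d[1, 0], d[1, 1] = E, W  # two cells pointing at each other
        with pytest.raises(ValueError, match="cycle"):
            flow_accumulation(make_grid(d, CS))


class TestStrahler:
    def _order_of_tree(self, depth):
        d, tree, outlet = binary_tree_directions(depth)
        direction = make_grid(d, CS)
        acc = make_grid(np.where(tree, 2, 1), CS)
        order = strahler_order(direction, acc, stream_threshold=2).values
        return order, tree, outlet

    def test_two_order1_tributaries_make_order2(self):
        order, _, outlet = self._order_of_tree(1)
        assert order[outlet] == 2

    @pytest.mark.parametrize("depth", [1, 2, 3])
    def test_binary_tree_outlet_order_matches_recursive_oracle(self, depth):
        order, tree, outlet = self._order_of_tree(depth)
        assert order[outlet] == strahler_merge_oracle(depth)
        assert (order[~tree] == 0).all()

    def test_unequal_junction_keeps_max(self):
        # order-2 stream joined by an order-1 side tributary stays order 2
        d, tree, outlet = binary_tree_directions(1, n_extra_rows=3)
        rows, _ = d.shape
        c = outlet[1]
        # side stream: single leaf joining the main stem two rows below the junction
        d[2, c + 1] = 5  # SW into (3, c)
        tree[2, c + 1] = True
        direction = make_grid(d, CS)
        acc = make_grid(np.where(tree, 2, 1), CS)
        order = strahler_order(direction, acc, stream_threshold=2).values
        assert order[3, c] == 2

    def test_order_never_decreases_downstream(self, small_result):
        rg = small_result.rivers
        order = np.asarray(rg.strahler.values)
        ds = _downstream(np.asarray(rg.flow_direction.values))
        flat = order.ravel()
        for c, d in enumerate(ds):
            if d >= 0 and flat[c] > 0 and flat[d] > 0:
                assert flat[d] >= flat[c]


class TestWidthClass:
    def test_default_map_order4_is_medium(self):
        g = make_grid(np.array([[0, 1, 3], [4, 5, 6]]), CS)
        wc = width_class(g).values
        assert wc[0, 0] == 0          # off-stream
        assert wc[0, 1] == wc[0, 2] == 1  # small
        assert wc[1, 0] == wc[1, 1] == 2  # medium
        assert wc[1, 2] == 3          # large

    def test_orders_above_map_take_largest_class(self):
        g = make_grid(np.array([[9]]), CS)
        assert width_class(g).values[0, 0] == 3

    def test_width_monotone_downstream_with_monotone_map(self, small_result):
        rg = small_result.rivers
        wc = np.asarray(rg.width_class.values).ravel()
        order = np.asarray(rg.strahler.values).ravel()
        ds = _downstream(np.asarray(rg.flow_direction.values))
        for c, d in enumerate(ds):
            if d >= 0 and order[c] > 0 and order[d] > 0:
                assert wc[d] >= wc[c]

    def test_determinism(self, rng):
        z = rng.standard_normal((20, 20)) * 10
        a = build_river_grid(make_grid(z, CS), stream_threshold=5)
        b = build_river_grid(make_grid(z.copy(), CS), stream_threshold=5)
        np.testing.assert_array_equal(a.strahler.values, b.strahler.values)
        np.testing.assert_array_equal(a.accumulation.values, b.accumulation.values)
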