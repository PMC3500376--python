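import numpy as np
import pytest

from corridorscope.circuit import (
    build_network,
    cumulative_current,
    current_map,
    kirchhoff_violation,
    slice_current,
    solve_pair,
)
from corridorscope.lcm import least_cost_path
from corridorscope.raster import GridSpec, RasterLayer


def resistance_layer(vals, cellsize=1.0, mask=None):
    vals = np.asarray(vals, dtype=float)
    spec = GridSpec(*vals.shape, cellsize, origin_y=vals.shape[0] * cellsize)
    return RasterLayer(spec, vals, "continuous", mask)


def dense_voltages(network, src_region, dst_region):
    """Independent dense-matrix solve of the same grounded system."""
    n = network.n_nodes
    lap = np.zeros((n, n))
    for u, v, g in zip(network.edge_src, network.edge_dst, network.edge_g):
        lap[u, u] += g
        lap[v, v] += g
        lap[u, v] -= g
        lap[v, u] -= g
    s, d = network.focal_nodes[src_region], network.focal_nodes[dst_region]
    keep = [i for i in range(n) if i != d]
    rhs = np.zeros(n)
    rhs[s] = 1.0
    v = np.zeros(n)
    v[keep] = np.linalg.solve(lap[np.ix_(keep, keep)], rhs[keep])
    return v


class TestBuildNetwork:
    def test_strip_contraction(self):
        layer = resistance_layer(np.ones((1, 3)))
        net = build_network(layer, [[(0, 0)], [(0, 2)]])
        assert net.n_nodes == 3  # 2 supernodes + 1 interior

    def test_3x3_edge_enumeration(self):
        layer = resistance_layer(np.ones((3, 3)))
        net = build_network(layer, [[(0, 0)]])
        # 12 orthogonal + 8 diagonal undirected edges, none internal to the 1-cell region
        assert len(net.edge_g) == 20

    def test_disconnected_pair_flagged(self):
        mask = np.ones((3, 3), dtype=bool)
        mask[:, 1] = False
        layer = resistance_layer(np.ones((3, 3)), mask=mask)
        net = build_network(layer, [[(0, 0)], [(0, 2)]])
        with pytest.raises(ValueError, match="different components"):
            solve_pair(net, 0, 1)

    def test_region_outside_mask_rejected(self):
        mask = np.ones((3, 3), dtype=bool)
        mask[0, 0] = False
        layer = resistance_layer(np.ones((3, 3)), mask=mask)
        with pytest.raises(ValueError, match="outside"):
            build_network(layer, [[(0, 0)]])

    def test_overlapping_regions_rejected(self):
        layer = resistance_layer(np.ones((3, 3)))
        with pytest.raises(ValueError, match="disjoint"):
            build_network(layer, [[(0, 0)], [(0, 0)]])


class TestSolvePair:
    def test_series_strip(self):
        # 1x3 strip, unit resistance, unit cells: two unit resistors in series
        layer = resistance_layer(np.ones((1, 3)))
        net = build_network(layer, [[(0, 0)], [(0, 2)]])
        sol = solve_pair(net, 0, 1)
        assert sol.r_eff == pytest.approx(2.0, abs=1e-10)

    def test_two_parallel_paths(self):
        # two disjoint 4-edge paths of unit resistors between the focal cells
        mask = np.ones((3, 3), dtype=bool)
        mask[1, 1] = False
        layer = resistance_layer(np.ones((3, 3)), mask=mask)
        net = build_network(layer, [[(1, 0)], [(1, 2)]], neighborhood=4)
        sol = solve_pair(net, 0, 1)
        assert sol.r_eff == pytest.approx(2.0, abs=1e-10)  # L/2 with L = 4

    @pytest.mark.parametrize("seed", range(5))
    def test_dense_solver_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 16))
        layer = resistance_layer(rng.uniform(0.01, 2.0, (n, n)))
        regions = [[(0, 0), (0, 1)], [(n - 1, n - 1)]]
        net = build_network(layer, regions)
        sol = solve_pair(net, 0, 1)
        oracle = dense_voltages(net, 0, 1)
        np.testing.assert_allclose(sol.voltages, oracle, atol=1e-8)

    def test_kirchhoff_conservation(self):
        rng = np.random.default_rng(7)
        layer = resistance_layer(rng.uniform(0.01, 1.0, (12, 12)))
        net = build_network(layer, [[(0, 0)], [(11, 11)]])
        sol = solve_pair(net, 0, 1)
        assert kirchhoff_violation(net, sol) < 1e-8

    def test_reciprocity(self):
        rng = np.random.default_rng(8)
        layer = resistance_layer(rng.uniform(0.01, 1.0, (10, 10)))
        net = build_network(layer, [[(0, 0)], [(9, 9)]])
        assert solve_pair(net, 0, 1).r_eff == pytest.approx(solve_pair(net, 1, 0).r_eff, abs=1e-8)

    def test_reff_bounded_by_lcp_cost(self):
        rng = np.random.default_rng(9)
        layer = resistance_layer(rng.uniform(0.01, 1.0, (12, 12)), cellsize=30.0)
        net = build_network(layer, [[(0, 0)], [(11, 11)]])
        r_eff = solve_pair(net, 0, 1).r_eff
        _, lcp = least_cost_path(layer, [(0, 0)], [(11, 11)])
        assert r_eff <= lcp + 1e-9


class TestCurrentMap:
    def test_series_strip_conservation(self):
        layer = resistance_layer(np.ones((1, 5)))
        net = build_network(layer, [[(0, 0)], [(0, 4)]])
        sol = solve_pair(net, 0, 1)
        cm = current_map(net, sol)
        np.testing.assert_allclose(cm.values[0], 1.0, atol=1e-10)

    def test_symmetric_paths_split_half(self):
        mask = np.ones((3, 3), dtype=bool)
        mask[1, 1] = False
        layer = resistance_layer(np.ones((3, 3)), mask=mask)
        net = build_network(layer, [[(1, 0)], [(1, 2)]], neighborhood=4)
        cm = current_map(net, solve_pair(net, 0, 1))
        assert cm.values[0, 1] == pytest.approx(0.5, abs=1e-10)
        assert cm.values[2, 1] == pytest.approx(0.5, abs=1e-10)

    def test_cut_audit_unit_flow(self):
        rng = np.random.default_rng(10)
        layer = resistance_layer(rng.uniform(0.01, 1.0, (8, 8)))
        net = build_network(layer, [[(0, 0)], [(7, 7)]])
        sol = solve_pair(net, 0, 1)
        # cut: columns 0-3 vs 4-7; net signed current across the cut equals injection
        side = np.zeros(net.n_nodes, dtype=bool)
        valid = net.node_of >= 0
        rr, cc = np.nonzero(valid)
        side[net.node_of[rr, cc]] = cc >= 4
        crossing = side[net.edge_src] != side[net.edge_dst]
        sign = np.where(side[net.edge_src], -1.0, 1.0)
        net_flow = np.sum(sol.edge_currents[crossing] * sign[crossing])
        assert net_flow == pytest.approx(1.0, abs=1e-8)

    def test_non_negative(self):
        rng = np.random.default_rng(11)
        layer = resistance_layer(rng.uniform(0.01, 1.0, (9, 9)))
        net = build_network(layer, [[(0, 0)], [(8, 8)]])
        cm = current_map(net, solve_pair(net, 0, 1))
        assert np.all(cm.values >= 0)


class TestCumulativeCurrent:
    def test_single_pair_equals_solve_pair(self):
        rng = np.random.default_rng(12)
        layer = resistance_layer(rng.uniform(0.01, 1.0, (8, 8)))
        regions = [[(0, 0)], [(7, 7)]]
        net = build_network(layer, regions)
        direct = current_map(net, solve_pair(net, 0, 1))
        cum = cumulative_current(layer, regions, [(0, 1)])
        np.testing.assert_allclose(cum.values, direct.values, atol=1e-12)

    def test_pair_reciprocity(self):
        rng = np.random.default_rng(13)
        layer = resistance_layer(rng.uniform(0.01, 1.0, (8, 8)))
        regions = [[(0, 0)], [(7, 7)]]
        ab = cumulative_current(layer, regions, [(0, 1)])
        ba = cumulative_current(layer, regions, [(1, 0)])
        np.testing.assert_allclose(ab.values, ba.values, atol=1e-8)

    def test_three_destination_additivity(self):
        rng = np.random.default_rng(14)
        layer = resistance_layer(rng.uniform(0.01, 1.0, (10, 10)))
        regions = [[(9, 4)], [(0, 0)], [(0, 5)], [(0, 9)]]
        pairs = [(0, 1), (0, 2), (0, 3)]
        total = cumulative_current(layer, regions, pairs)
        summed = np.zeros((10, 10))
        for pair in pairs:
            summed += cumulative_current(layer, regions, [pair]).values
        np.testing.assert_allclose(total.values, summed, atol=1e-10)

    def test_too_few_regions(self):
        layer = resistance_layer(np.ones((4, 4)))
        with pytest.raises(ValueError, match="two focal regions"):
            cumulative_current(layer, [[(0, 0)]], [])


@pytest.fixture(scope="module")
def uniform_two_patch():
    layer = resistance_layer(np.ones((20, 30)), cellsize=30.0)
    regions = [
        [(r, c) for r in range(9, 12) for c in range(0, 3)],
        [(r, c) for r in range(9, 12) for c in range(27, 30)],
    ]
    cum = cumulative_current(layer, regions, [(0, 1)])
    return cum, regions


class TestSliceCurrent:
    def test_p100_all_and_connected(self, uniform_two_patch):
        cum, regions = uniform_two_patch
        mask, connected = slice_current(cum, 100, regions)
        assert mask.cells.all()
        assert connected is True

    def test_focal_cells_inside_mask_small_p(self, uniform_two_patch):
        cum, regions = uniform_two_patch
        mask, _ = slice_current(cum, 1, regions)
        for region in regions:
            cells = np.asarray(region)
            assert mask.cells[cells[:, 0], cells[:, 1]].all()

    def test_connection_threshold_sweep(self, uniform_two_patch):
        cum, regions = uniform_two_patch
        first_connected = None
        prev_connected = False
        for p in (1, 5, 10, 15, 20, 30, 50):
            _, connected = slice_current(cum, p, regions)
            if connected and first_connected is None:
                first_connected = p
            assert not (prev_connected and not connected)  # once connected, stays connected
            prev_connected = connected
        assert first_connected is not None and first_connected > 1

    def test_constant_map_rejected(self):
        layer = resistance_layer(np.ones((4, 4)))
        with pytest.raises(ValueError):
            slice_current(layer, 10)
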