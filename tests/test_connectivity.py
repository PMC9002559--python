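import networkx as nx
import numpy as np
import pytest

import invasipath as ip
from invasipath.prep import SQRT2


def nx_cost_distance(resistance, cs, sources):
    """Independent Dijkstra oracle with mean-endpoint edge costs."""
    nrows, ncols = resistance.shape
    g = nx.Graph()
    for r in range(nrows):
        for c in range(ncols):
            g.add_node((r, c))
            for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrows and 0 <= cc < ncols:
                    step = cs * (SQRT2 if dr and dc else 1.0)
                    w = 0.5 * (resistance[r, c] + resistance[rr, cc]) * step
                    g.add_edge((r, c), (rr, cc), weight=w)
    lengths = nx.multi_source_dijkstra_path_length(g, set(sources))
    out = np.full(resistance.shape, np.inf)
    for (r, c), d in lengths.items():
        out[r, c] = d
    return out


def res_layer(arr, cs=100.0):
    return ip.ResistanceSurface(
        resistance=ip.RasterLayer(np.asarray(arr, float), cell_size=cs,
                                  kind="continuous")
    )


def square_core(cid, r0, c0, size=1):
    cells = np.array(
        [(r0 + i, c0 + j) for i in range(size) for j in range(size)]
    )
    return ip.CorePatch(id=cid, cells=cells, area_km2=size * size * 0.01,
                        centroid=(0.0, 0.0))


class TestResistance:
    @pytest.mark.parametrize("p,expect", [(0.0, 1.0), (0.25, 0.75)])
    def test_inversion(self, p, expect):
        layer = ip.RasterLayer(np.full((4, 4), p), cell_size=100.0)
        surf = ip.build_resistance(layer)
        assert np.allclose(surf.resistance.values, expect)

    def test_floor_prevents_free_travel(self):
        layer = ip.RasterLayer(np.ones((4, 4)), cell_size=100.0)
        surf = ip.build_resistance(layer, epsilon=1e-3)
        assert np.allclose(surf.resistance.values, 1e-3)

    def test_out_of_range_probability_rejected(self):
        layer = ip.RasterLayer(np.full((3, 3), 1.2), cell_size=100.0)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            ip.build_resistance(layer)

    def test_nodata_preserved(self):
        vals = np.full((3, 3), 0.5)
        vals[1, 1] = np.nan
        surf = ip.build_resistance(ip.RasterLayer(vals, cell_size=100.0))
        assert np.isnan(surf.resistance.values[1, 1])


class TestCostDistance:
    def test_uniform_resistance_gives_octile_distance(self):
        surf = res_layer(np.ones((6, 8)))
        cost, _ = ip.cost_distance(surf, {(2, 3)})
        for r in range(6):
            for c in range(8):
                dr, dc = abs(r - 2), abs(c - 3)
                octile = 100.0 * (max(dr, dc) - min(dr, dc)) \
                    + 100.0 * SQRT2 * min(dr, dc)
                assert cost.values[r, c] == pytest.approx(octile)

    def test_wall_disconnects(self):
        vals = np.ones((3, 3))
        vals[:, 1] = np.nan
        cost, _ = ip.cost_distance(res_layer(vals), {(1, 0)})
        assert np.isinf(cost.values[1, 2])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        r = rng.uniform(0.05, 1.0, size=(6, 6))
        cost, _ = ip.cost_distance(res_layer(r), {(0, 0)})
        want = nx_cost_distance(r, 100.0, {(0, 0)})
        np.testing.assert_allclose(cost.values, want, rtol=1e-10)

    def test_all_sources_on_nodata_rejected(self):
        vals = np.ones((3, 3))
        vals[0, 0] = np.nan
        with pytest.raises(ValueError, match="nodata"):
            ip.cost_distance(res_layer(vals), {(0, 0)})

    def test_backlinks_reconstruct_a_shortest_path(self):
        rng = np.random.default_rng(3)
        r = rng.uniform(0.1, 1.0, size=(5, 5))
        surf = res_layer(r)
        cost, pred = ip.cost_distance(surf, {(0, 0)})
        # walk back from the far corner, accumulating edge costs
        node = 4 * 5 + 4
        total = 0.0
        while pred[node] >= 0:
            nxt = int(pred[node])
            r0, c0 = divmod(node, 5)
            r1, c1 = divmod(nxt, 5)
            assert max(abs(r0 - r1), abs(c0 - c1)) == 1
            step = 100.0 * (SQRT2 if (r0 != r1 and c0 != c1) else 1.0)
            total += 0.5 * (r[r0, c0] + r[r1, c1]) * step
            node = nxt
        assert total == pytest.approx(cost.values[4, 4])


class TestCorridorNetwork:
    def test_two_cores_one_straight_corridor(self):
        surf = res_layer(np.ones((5, 9)))
        cores = [square_core(1, 2, 0), square_core(2, 2, 8)]
        corridors = ip.build_corridor_network(cores, surf)
        assert len(corridors) == 1
        cor = corridors[0]
        assert cor.core_pair == (1, 2)
        rows = {r for r, _ in cor.lcp_cells}
        assert rows == {2}  # straight line on uniform resistance
        assert cor.lcp_cells[0] == (2, 0) and cor.lcp_cells[-1] == (2, 8)
        assert cor.cost == pytest.approx(8 * 100.0)
        assert cor.length_km == pytest.approx(0.8)

    def test_three_collinear_cores_two_corridors(self):
        surf = res_layer(np.ones((5, 17)))
        cores = [square_core(1, 2, 0), square_core(2, 2, 8),
                 square_core(3, 2, 16)]
        corridors = ip.build_corridor_network(cores, surf)
        pairs = {c.core_pair for c in corridors}
        # outer pair's allocation regions never touch
        assert pairs == {(1, 2), (2, 3)}

    def test_lcp_cells_are_8_connected_and_span_cores(self, rng):
        r = rng.uniform(0.05, 1.0, size=(12, 12))
        surf = res_layer(r)
        cores = [square_core(1, 0, 0, 2), square_core(2, 9, 9, 2)]
        corridors = ip.build_corridor_network(cores, surf)
        for cor in corridors:
            for (r0, c0), (r1, c1) in zip(cor.lcp_cells, cor.lcp_cells[1:]):
                assert max(abs(r0 - r1), abs(c0 - c1)) == 1

    def test_cost_symmetry(self, rng):
        r = rng.uniform(0.05, 1.0, size=(10, 10))
        surf = res_layer(r)
        a, b = square_core(1, 0, 0), square_core(2, 9, 9)
        c_ab = ip.build_corridor_network([a, b], surf)[0].cost
        c_ba = ip.build_corridor_network([b, a], surf)[0].cost
        assert c_ab == pytest.approx(c_ba)

    def test_triangle_inequality_over_core_costs(self, rng):
        r = rng.uniform(0.05, 1.0, size=(12, 12))
        surf = res_layer(r)
        cores = [square_core(1, 0, 0), square_core(2, 0, 11),
                 square_core(3, 11, 5)]
        cost = {}
        for i in range(3):
            for j in range(i + 1, 3):
                cs = ip.build_corridor_network(
                    [cores[i], cores[j]], surf
                )
                cost[(i, j)] = cs[0].cost
        assert cost[(0, 2)] <= cost[(0, 1)] + cost[(1, 2)] + 1e-9

    def test_raising_resistance_never_cheapens_paths(self, rng):
        r = rng.uniform(0.05, 0.8, size=(10, 10))
        surf_lo = res_layer(r.copy())
        r_hi = r.copy()
        r_hi[4:6, :] += 0.2
        surf_hi = res_layer(r_hi)
        cores = [square_core(1, 0, 0), square_core(2, 9, 9)]
        lo = ip.build_corridor_network(cores, surf_lo)[0].cost
        hi = ip.build_corridor_network(cores, surf_hi)[0].cost
        assert hi >= lo - 1e-9

    def test_passable_surface_yields_connected_graph(self, small_bundle):
        import networkx as nxg

        prob = small_bundle["truth"].probability
        surf = ip.build_resistance(prob)
        binary = prob.copy_with((prob.values > 0.5).astype(float),
                                kind="categorical")
        _, cores = ip.extract_cores(binary, min_area_km2=0.03)
        if len(cores) < 2:
            pytest.skip("scenario produced fewer than 2 cores")
        corridors = ip.build_corridor_network(cores, surf)
        g = nxg.Graph()
        g.add_nodes_from(c.id for c in cores)
        g.add_edges_from(c.core_pair for c in corridors)
        assert nxg.is_connected(g)

    def test_fewer_than_two_cores_rejected(self):
        surf = res_layer(np.ones((5, 5)))
        with pytest.raises(ValueError, match="at least 2"):
            ip.build_corridor_network([square_core(1, 0, 0)], surf)


class TestCorridorSurface:
    def _setup(self, rng):
        r = rng.uniform(0.05, 1.0, size=(8, 8))
        surf = res_layer(r)
        a, b = square_core(1, 0, 0), square_core(2, 7, 7)
        cost_a, _ = ip.cost_distance(surf, {(0, 0)})
        cost_b, _ = ip.cost_distance(surf, {(7, 7)})
        lcp = ip.build_corridor_network([a, b], surf)[0]
        return cost_a, cost_b, lcp

    def test_lcp_cells_score_zero_and_min_is_zero(self, rng):
        cost_a, cost_b, lcp = self._setup(rng)
        out = ip.corridor_surface(cost_a, cost_b, lcp.cost)
        assert np.nanmin(out.values) == pytest.approx(0.0, abs=1e-9)
        for r, c in lcp.lcp_cells:
            assert out.values[r, c] == pytest.approx(0.0, abs=1e-9)

    def test_zero_cutoff_keeps_only_lcp_band(self, rng):
        cost_a, cost_b, lcp = self._setup(rng)
        out = ip.corridor_surface(cost_a, cost_b, lcp.cost, cutoff=1e-9)
        kept = {(int(r), int(c)) for r, c in zip(*np.nonzero(~np.isnan(out.values)))}
        assert set(lcp.lcp_cells) <= kept

    def test_overstated_lcp_cost_rejected(self, rng):
        cost_a, cost_b, lcp = self._setup(rng)
        with pytest.raises(ValueError, match="negative"):
            ip.corridor_surface(cost_a, cost_b, lcp.cost + 10.0)

    def test_mosaic_minimum_is_zero_on_every_lcp(self, rng):
        r = rng.uniform(0.05, 1.0, size=(10, 12))
        surf = res_layer(r)
        cores = [square_core(1, 0, 0), square_core(2, 9, 11),
                 square_core(3, 0, 11)]
        corridors = ip.build_corridor_network(cores, surf)
        mosaic = ip.corridor_mosaic(cores, surf)
        assert np.nanmin(mosaic.values) == pytest.approx(0.0, abs=1e-9)
        for cor in corridors:
            for rr, cc in cor.lcp_cells:
                assert mosaic.values[rr, cc] == pytest.approx(0.0, abs=1e-9)
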