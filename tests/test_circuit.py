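import numpy as np
import pandas as pd
import pytest

from conftest import random_surface
from ibrscape.circuit import (
    DisconnectedError,
    effective_resistance,
    effective_resistance_dense_oracle,
    flat_resistance_matrix,
    grid_graph,
    resistance_matrix,
)
from ibrscape.raster import ResistanceSurface, uniform_surface


class TestGridGraph:
    def test_two_cell_path_has_unit_edge(self):
        g = grid_graph(ResistanceSurface(np.ones((1, 2)), 1.0), 4)
        adj = g.adjacency()
        assert adj.nnz == 2  # one undirected edge
        assert adj[0, 1] == pytest.approx(1.0)

    def test_2x2_edge_census_with_diagonals(self):
        g = grid_graph(ResistanceSurface(np.ones((2, 2)), 1.0), 8)
        adj = g.adjacency().toarray()
        # 4 cardinal edges of conductance 1, 2 diagonal edges of 1/sqrt(2)
        vals = adj[np.triu_indices(4, 1)]
        vals = vals[vals > 0]
        assert sorted(np.round(vals, 10)) == pytest.approx(
            sorted([1.0] * 4 + [1 / np.sqrt(2)] * 2)
        )

    def test_average_resistance_rule(self):
        g = grid_graph(ResistanceSurface(np.array([[1.0, 3.0]]), 1.0), 4)
        assert g.adjacency()[0, 1] == pytest.approx(0.5)

    def test_interior_degree_is_eight(self):
        g = grid_graph(ResistanceSurface(np.ones((5, 5)), 1.0), 8)
        centre = g.node_of[2, 2]
        assert g.adjacency()[centre].nnz == 8

    def test_nodata_cells_carry_no_node(self):
        res = np.ones((3, 3))
        res[1, 1] = np.nan
        g = grid_graph(ResistanceSurface(res, 1.0), 4)
        assert g.n_nodes == 8
        assert g.node_of[1, 1] == -1

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            grid_graph(ResistanceSurface(np.ones((1, 1)), 1.0), 4)


class TestEffectiveResistance:
    def test_series_path(self):
        g = grid_graph(ResistanceSurface(np.ones((1, 3)), 1.0), 4)
        assert effective_resistance(g, (0, 2)) == pytest.approx(2.0, abs=1e-10)

    def test_square_parallel_paths(self):
        g = grid_graph(ResistanceSurface(np.ones((2, 2)), 1.0), 4)
        assert effective_resistance(g, (0, 3)) == pytest.approx(1.0, abs=1e-10)

    def test_square_with_diagonals(self):
        g = grid_graph(ResistanceSurface(np.ones((2, 2)), 1.0), 8)
        assert effective_resistance(g, (0, 3)) == pytest.approx(
            2 - np.sqrt(2), abs=1e-10
        )

    def test_disconnected_pair_signalled(self):
        res = np.ones((1, 5))
        res[0, 2] = np.nan
        g = grid_graph(ResistanceSurface(res, 1.0), 4)
        with pytest.raises(DisconnectedError):
            effective_resistance(g, (0, 3))

    def test_identical_focal_nodes_rejected(self):
        g = grid_graph(ResistanceSurface(np.ones((2, 2)), 1.0), 4)
        with pytest.raises(ValueError):
            effective_resistance(g, (1, 1))

    def test_sparse_matches_dense_oracle_on_random_surfaces(self, rng):
        for _ in range(10):
            surf = random_surface(rng, 6, 7)
            g = grid_graph(surf, 8)
            a, b = rng.choice(g.n_nodes, size=2, replace=False)
            sparse = effective_resistance(g, (int(a), int(b)))
            dense = effective_resistance_dense_oracle(g, (int(a), int(b)))
            assert sparse == pytest.approx(dense, rel=1e-8)

    def test_triangle_of_unit_conductances(self):
        # 8-connected 2x2 with one nodata corner = a 3-node cycle with
        # two unit cardinal edges and one diagonal edge
        res = np.ones((2, 2))
        res[1, 1] = np.nan
        g = grid_graph(ResistanceSurface(res, 1.0), 8)
        r = effective_resistance(g, (0, 2))
        oracle = effective_resistance_dense_oracle(g, (0, 2))
        assert r == pytest.approx(oracle, rel=1e-10)


class TestMetricProperties:
    def test_metric_axioms_on_random_graph(self, rng):
        surf = random_surface(rng, 5, 5)
        g = grid_graph(surf, 8)
        nodes = rng.choice(g.n_nodes, size=4, replace=False)
        r = {}
        for i in nodes:
            for j in nodes:
                if i < j:
                    r[(i, j)] = effective_resistance(g, (int(i), int(j)))
                    assert r[(i, j)] > 0
        get = lambda a, b: r[(min(a, b), max(a, b))] if a != b else 0.0
        for a in nodes:
            for b in nodes:
                for c in nodes:
                    assert get(a, c) <= get(a, b) + get(b, c) + 1e-9

    def test_rayleigh_monotonicity(self, rng):
        surf = random_surface(rng, 4, 4)
        g = grid_graph(surf, 8)
        base = effective_resistance(g, (0, g.n_nodes - 1))
        for _ in range(5):
            res2 = surf.resistance.copy()
            r_, c_ = rng.integers(0, 4, size=2)
            res2[r_, c_] *= 1.0 + rng.uniform(0.1, 3.0)
            g2 = grid_graph(ResistanceSurface(res2, 1.0), 8)
            assert effective_resistance(g2, (0, g2.n_nodes - 1)) >= base - 1e-12

    def test_exact_scaling_with_resistance(self, rng):
        surf = random_surface(rng, 4, 5)
        scaled = ResistanceSurface(surf.resistance * 3.5, 1.0)
        g1, g2 = grid_graph(surf, 8), grid_graph(scaled, 8)
        r1 = effective_resistance(g1, (0, 10))
        r2 = effective_resistance(g2, (0, 10))
        assert r2 == pytest.approx(3.5 * r1, rel=1e-12)


def _xy(points, index):
    return pd.DataFrame(points, columns=["x", "y"], index=index)


class TestResistanceMatrix:
    def test_symmetric_zero_diagonal(self, rng):
        surf = random_surface(rng, 8, 8)
        xy = _xy([(1.5, 1.5), (6.5, 2.5), (3.5, 6.5)], ["a", "b", "c"])
        m = resistance_matrix(surf, xy)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 0)

    def test_matches_pairwise_single_solves(self, rng):
        surf = random_surface(rng, 6, 6)
        xy = _xy([(0.5, 0.5), (5.5, 0.5), (2.5, 5.5)], ["a", "b", "c"])
        m = resistance_matrix(surf, xy)
        g = grid_graph(surf, 8)
        for i, j, ri, rj in [(0, 1, (5, 0), (5, 5)), (0, 2, (5, 0), (0, 2))]:
            single = effective_resistance(
                g, (int(g.node_of[ri]), int(g.node_of[rj]))
            )
            assert m.values[i, j] == pytest.approx(single, rel=1e-8)

    def test_duplicate_cells_rejected(self):
        surf = uniform_surface(5, 5, 1.0)
        xy = _xy([(1.1, 1.1), (1.2, 1.2)], ["a", "b"])
        with pytest.raises(ValueError, match="same raster cell"):
            resistance_matrix(surf, xy)

    def test_uniform_scenario_scaling(self):
        xy = _xy([(2.0, 2.0), (17.0, 3.0), (9.0, 16.0)], ["a", "b", "c"])
        s1 = uniform_surface(20, 20, 1.0, resistance=1.0)
        s5 = uniform_surface(20, 20, 1.0, resistance=5.0)
        m1 = resistance_matrix(s1, xy)
        m5 = resistance_matrix(s5, xy)
        assert np.allclose(m5.values, 5.0 * m1.values, rtol=1e-12)

    def test_disconnected_pair_is_inf(self):
        res = np.ones((3, 5))
        res[:, 2] = np.nan
        surf = ResistanceSurface(res, 1.0)
        xy = _xy([(0.5, 1.5), (4.5, 1.5)], ["a", "b"])
        m = resistance_matrix(surf, xy)
        assert np.isinf(m.values[0, 1])

    def test_flat_matrix_equals_uniform_resistance_matrix(self):
        xy = _xy([(0.0, 0.0), (3000.0, 0.0), (1500.0, 2500.0)], ["a", "b", "c"])
        flat = flat_resistance_matrix(xy, cellsize=500.0, buffer=1000.0)
        assert flat.kind == "flat_resistance"
        assert np.allclose(flat.values, flat.values.T)
        assert (flat.values[np.triu_indices(3, 1)] > 0).all()
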