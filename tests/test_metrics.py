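import networkx as nx
import numpy as np
import pytest

from covnet import (
    betweenness_and_degree,
    characteristic_path_length,
    clustering_coefficient,
    generate_random_ensemble,
    identify_hubs,
    small_worldness,
)
from covnet.metrics import NodalMetrics, RandomEnsemble
from covnet.netbuild import BinaryGraph

from conftest import graph_from_edges, random_graph
from oracles import brute_betweenness, brute_clustering, brute_hubs, brute_path_length


def from_networkx(graph):
    nodes = sorted(graph.nodes())
    adjacency = nx.to_numpy_array(graph, nodelist=nodes, dtype=int)
    return BinaryGraph(roi_labels=[str(n) for n in nodes], adjacency=adjacency)


class TestClustering:
    def test_triangle_all_one(self):
        g = graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        nodal, mean = clustering_coefficient(g)
        np.testing.assert_allclose(nodal, 1.0)
        assert mean == 1.0

    def test_star_all_zero(self):
        g = graph_from_edges(6, [(0, i) for i in range(1, 6)])
        nodal, mean = clustering_coefficient(g)
        np.testing.assert_allclose(nodal, 0.0)
        assert mean == 0.0

    def test_five_node_hand_graph(self):
        # {AB, BC, CA, CD, DE}: triangle on ABC with a pendant path
        g = graph_from_edges(5, [(0, 1), (1, 2), (0, 2), (2, 3), (3, 4)])
        nodal, mean = clustering_coefficient(g)
        expected_nodal, expected_mean = brute_clustering(g.adjacency)
        np.testing.assert_allclose(nodal, expected_nodal)
        assert mean == pytest.approx(expected_mean)
        # C node (index 2) has neighbors {A, B, D}, one of 3 pairs linked
        assert nodal[2] == pytest.approx(1 / 3)


class TestPathLength:
    def test_complete_graph_is_one(self):
        for n in (3, 5, 8):
            g = graph_from_edges(n, [(i, j) for i in range(n) for j in range(i + 1, n)])
            assert characteristic_path_length(g) == pytest.approx(1.0)

    def test_three_node_path(self):
        g = graph_from_edges(3, [(0, 1), (1, 2)])
        assert characteristic_path_length(g) == pytest.approx(4 / 3)

    def test_disjoint_triangles_component_mode(self):
        g = graph_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        assert characteristic_path_length(g, mode="component") == pytest.approx(1.0)

    def test_harmonic_mode_penalizes_disconnection(self):
        connected = graph_from_edges(4, [(0, 1), (1, 2), (2, 3), (0, 3)])
        split = graph_from_edges(4, [(0, 1), (2, 3)])
        assert characteristic_path_length(
            split, mode="harmonic"
        ) > characteristic_path_length(connected, mode="harmonic")

    def test_empty_graph_rejected(self):
        g = graph_from_edges(4, [(0, 1)])
        g.adjacency[:] = 0
        with pytest.raises(ValueError, match="empty"):
            characteristic_path_length(g)

    def test_unknown_mode_rejected(self):
        g = graph_from_edges(3, [(0, 1)])
        with pytest.raises(ValueError, match="mode"):
            characteristic_path_length(g, mode="weird")

    def test_non_increasing_under_edge_addition(self):
        rng = np.random.default_rng(3)
        g = graph_from_edges(8, [(i, i + 1) for i in range(7)])
        previous = characteristic_path_length(g)
        missing = [(i, j) for i in range(8) for j in range(i + 2, 8)]
        rng.shuffle(missing)
        for i, j in missing[:10]:
            g.adjacency[i, j] = g.adjacency[j, i] = 1
            current = characteristic_path_length(g)
            assert current <= previous + 1e-12
            previous = current


class TestRandomEnsemble:
    def test_triangle_returns_copies_with_warning(self):
        g = graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        with pytest.warns(UserWarning, match="no legal"):
            ensemble = generate_random_ensemble(g, 3, seed=0)
        for member in ensemble.members:
            np.testing.assert_array_equal(member.adjacency, g.adjacency)

    def test_degree_sequence_preserved_exactly(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            g = random_graph(12, rng)
            ensemble = generate_random_ensemble(g, 4, seed=int(rng.integers(1 << 30)))
            for member in ensemble.members:
                np.testing.assert_array_equal(member.degrees, g.degrees)
                assert member.edge_count == g.edge_count

    def test_ring_lattice_randomization_lowers_clustering(self):
        g = from_networkx(nx.watts_strogatz_graph(20, 4, 0.0, seed=1))
        c_input = clustering_coefficient(g)[1]
        means = []
        for seed in range(5):
            ensemble = generate_random_ensemble(g, 5, seed=seed)
            means.append(
                np.mean([clustering_coefficient(m)[1] for m in ensemble.members])
            )
        assert np.mean(means) < c_input

    def test_determinism(self):
        g = random_graph(15, np.random.default_rng(5))
        e1 = generate_random_ensemble(g, 3, seed=7)
        e2 = generate_random_ensemble(g, 3, seed=7)
        for m1, m2 in zip(e1.members, e2.members):
            np.testing.assert_array_equal(m1.adjacency, m2.adjacency)


class TestSmallWorldness:
    def test_self_ensemble_identity(self):
        g = random_graph(10, np.random.default_rng(6))
        ensemble = RandomEnsemble(
            members=[g, g, g], iterations_per_edge=0, seed=None
        )
        gm = small_worldness(g, ensemble)
        assert gm.gamma == pytest.approx(1.0)
        assert gm.lam == pytest.approx(1.0)
        assert gm.sigma == pytest.approx(1.0)

    def test_sigma_equals_gamma_over_lambda(self):
        g = random_graph(12, np.random.default_rng(7))
        ensemble = generate_random_ensemble(g, 5, seed=2)
        gm = small_worldness(g, ensemble)
        assert gm.sigma == pytest.approx(gm.gamma / gm.lam)

    def test_empty_ensemble_rejected(self):
        g = random_graph(6, np.random.default_rng(8))
        with pytest.raises(ValueError, match="empty"):
            small_worldness(g, RandomEnsemble(members=[], iterations_per_edge=0, seed=None))

    def test_watts_strogatz_sigma_above_one(self):
        # single-instance smoke check; the calibrated band test is in acceptance
        g = from_networkx(nx.connected_watts_strogatz_graph(60, 8, 0.1, seed=3))
        ensemble = generate_random_ensemble(g, 8, seed=4)
        assert small_worldness(g, ensemble).sigma > 1.3


class TestBetweennessAndDegree:
    def test_star_center(self):
        g = graph_from_edges(6, [(0, i) for i in range(1, 6)])
        nodal = betweenness_and_degree(g)
        assert nodal.betweenness[0] == pytest.approx(1.0)
        np.testing.assert_allclose(nodal.betweenness[1:], 0.0)
        assert nodal.degree[0] == 5

    def test_complete_graph_zero(self):
        g = graph_from_edges(5, [(i, j) for i in range(5) for j in range(i + 1, 5)])
        np.testing.assert_allclose(betweenness_and_degree(g).betweenness, 0.0)

    def test_four_node_path(self):
        # A-B-C-D: B and C each lie on 2 of the 3 pair paths -> 2/3 normalized
        g = graph_from_edges(4, [(0, 1), (1, 2), (2, 3)])
        nodal = betweenness_and_degree(g)
        np.testing.assert_allclose(nodal.betweenness, [0, 2 / 3, 2 / 3, 0])

    def test_degree_sums_to_twice_edges(self):
        g = random_graph(10, np.random.default_rng(9))
        nodal = betweenness_and_degree(g)
        assert nodal.degree.sum() == 2 * g.edge_count

    def test_low_degree_nodes_zero_betweenness(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            g = random_graph(9, rng, p=0.3)
            nodal = betweenness_and_degree(g)
            assert np.all(nodal.betweenness[nodal.degree <= 1] == 0)


class TestHubs:
    def make_nodal(self, betweenness, labels=None):
        b = np.asarray(betweenness, dtype=float)
        labels = labels or [f"N{i}" for i in range(b.size)]
        return NodalMetrics(
            roi_labels=labels,
            degree=np.zeros(b.size, dtype=int),
            betweenness=b,
            is_hub=np.zeros(b.size, dtype=bool),
        )

    def test_degenerate_equal_betweenness_no_hubs(self):
        assert identify_hubs(self.make_nodal([0.3] * 8)) == set()

    def test_star_center_only_hub(self):
        g = graph_from_edges(10, [(0, i) for i in range(1, 10)])
        nodal = betweenness_and_degree(g)
        # oracle on {1, 0 x 9}: mean 0.1, sd 0.3, cut 0.7 -> center only
        assert nodal.hub_labels() == {"N0"}
        assert identify_hubs(nodal) == {"N0"}

    def test_barbell_two_centers(self):
        # two stars joined by a bridge between their centers
        edges = [(0, i) for i in range(2, 6)] + [(1, i) for i in range(6, 10)] + [(0, 1)]
        g = graph_from_edges(10, edges)
        nodal = betweenness_and_degree(g)
        expected = brute_hubs(brute_betweenness(g.adjacency), g.roi_labels)
        assert nodal.hub_labels() == expected == {"N0", "N1"}


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("seed", range(40))
    def test_all_metrics_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        g = random_graph(n, rng)
        nodal_c, mean_c = clustering_coefficient(g)
        oracle_c, oracle_mean = brute_clustering(g.adjacency)
        np.testing.assert_allclose(nodal_c, oracle_c, atol=1e-9)
        assert mean_c == pytest.approx(oracle_mean, abs=1e-9)
        for mode in ("component", "harmonic"):
            assert characteristic_path_length(g, mode=mode) == pytest.approx(
                brute_path_length(g.adjacency, mode=mode), abs=1e-9
            )
        nodal = betweenness_and_degree(g)
        np.testing.assert_allclose(
            nodal.betweenness, brute_betweenness(g.adjacency), atol=1e-9
        )
        assert nodal.hub_labels() == brute_hubs(
            brute_betweenness(g.adjacency), g.roi_labels
        )
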