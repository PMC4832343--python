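"""Network construction, shortest paths, betweenness and summaries against
independent oracles (exhaustive enumeration and networkx)."""

import numpy as np
import pytest

from fcnet.network import (
    all_pairs_shortest_paths,
    build_network,
    contact_edges,
    edge_betweenness,
    network_summary,
    reconstruct_path,
    shortest_pathway,
    site_path_statistics,
    top_degree_table,
    site_degree_sum,
    weighted_degree,
    write_edge_list,
    write_graphml,
)
from fcnet.synthetic import make_ring_pathway_system, make_two_block_system, sample_trajectory
from fcnet.correlation import correlation_matrix
from fcnet.trajectory import make_node_map

from conftest import (
    correlation_from_matrix,
    enumerate_shortest,
    net_from_edges,
    random_weighted_graph,
    simple_residue,
    toy_trajectory,
    unit_length_net,
)


def _two_residue_traj(distances, chains=("A", "B")):
    """Two single-atom residues whose separation is scripted per frame."""
    rows = (simple_residue(0, 1, "ALA", chains[0], [("CA", "C", 12.0)])
            + simple_residue(1, 2, "ALA", chains[1], [("CA", "C", 12.0)]))
    frames = [[[0.0, 0, 0], [float(d), 0, 0]] for d in distances]
    return toy_trajectory(rows, frames)


class TestContactEdges:
    def test_occupancy_above_threshold_is_edge(self):
        traj = _two_residue_traj([3.0] * 80 + [9.0] * 20)
        edges = contact_edges(traj)
        assert len(edges) == 1
        assert edges["occupancy"][0] == pytest.approx(0.80)

    def test_exact_threshold_is_not_edge(self):
        traj = _two_residue_traj([3.0] * 75 + [9.0] * 25)
        assert len(contact_edges(traj)) == 0

    def test_cutoff_boundary_strict(self):
        # distance exactly 4.5 is not a contact ("closer than")
        traj = _two_residue_traj([4.5] * 10)
        assert len(contact_edges(traj)) == 0
        traj = _two_residue_traj([4.4999] * 10)
        assert len(contact_edges(traj)) == 1

    def test_chain_adjacent_pair_excluded(self):
        rows = (simple_residue(0, 1, "ALA", "A", [("CA", "C", 12.0)])
                + simple_residue(1, 2, "ALA", "A", [("CA", "C", 12.0)]))
        frames = [[[0.0, 0, 0], [3.0, 0, 0]]] * 10
        traj = toy_trajectory(rows, frames)
        assert len(contact_edges(traj)) == 0

    def test_minimum_over_heavy_atoms(self):
        rows = (simple_residue(0, 1, "ALA", "A",
                               [("CA", "C", 12.0), ("CB", "C", 12.0)])
                + simple_residue(1, 2, "ALA", "B", [("CA", "C", 12.0)]))
        # CA far, CB close: the minimum decides
        frames = [[[0.0, 0, 0], [6.0, 0, 0], [9.0, 0, 0]]] * 4
        traj = toy_trajectory(rows, frames)
        assert len(contact_edges(traj)) == 1


class TestBuildNetwork:
    def test_path_length_values(self):
        net = net_from_edges([(0, 1, 1.0), (1, 2, 0.5)])
        w = dict(zip(zip(net.edges["node_i"], net.edges["node_j"]),
                     net.edges["length"]))
        assert w[(0, 1)] == pytest.approx(0.0)
        assert w[(1, 2)] == pytest.approx(np.log(2))

    def test_zero_and_nan_correlations_dropped(self):
        import pandas as pd

        C = correlation_from_matrix(np.array([
            [1.0, 0.0, np.nan], [0.0, 1.0, 0.5], [np.nan, 0.5, 1.0]]))
        edges = pd.DataFrame(dict(node_i=[0, 0, 1], node_j=[1, 2, 2],
                                  occupancy=[1.0, 1.0, 1.0]))
        with pytest.warns(RuntimeWarning, match="dropped"):
            net = build_network(C, edges)
        assert net.n_edges == 1

    def test_negative_correlation_uses_magnitude(self):
        net = net_from_edges([(0, 1, -0.5)])
        assert net.edges["length"][0] == pytest.approx(np.log(2))
        assert weighted_degree(net, 0) == pytest.approx(0.5)

    def test_planted_edge_weights_match_sample_correlations(self):
        sys_ = make_two_block_system(n_frames=2000, seed=13)
        traj = sample_trajectory(sys_)
        nm = make_node_map(traj.topology)
        C = correlation_matrix(traj, nm)
        net = build_network(C, contact_edges(traj), chains=nm.chain_ids)
        for _, e in net.edges.iterrows():
            i = nm.labels.index(net.labels[int(e["node_i"])])
            j = nm.labels.index(net.labels[int(e["node_j"])])
            assert e["length"] == pytest.approx(-np.log(abs(C.C[i, j])))


class TestDegrees:
    def test_isolated_node_zero(self):
        net = net_from_edges([(0, 1, 0.9)], n=3)
        assert weighted_degree(net, 2) == 0.0

    def test_sum_of_incident_magnitudes(self):
        net = net_from_edges([(0, 1, 0.9), (0, 2, 0.8)])
        assert weighted_degree(net, 0) == pytest.approx(1.7)

    def test_matches_brute_force_and_permutation_invariant(self):
        rng = np.random.default_rng(1)
        edges = random_weighted_graph(rng, 12)
        net = net_from_edges(edges, n=12)
        deg = weighted_degree(net)
        for v in range(12):
            expected = sum(abs(c) for i, j, c in edges if v in (i, j))
            assert deg[v] == pytest.approx(expected)
        total = site_degree_sum(net, [f"N{i:03d}" for i in range(12)])
        assert total == pytest.approx(2 * sum(abs(c) for *_, c in edges))

    def test_top_table_sorted(self):
        net = net_from_edges([(0, 1, 0.9), (0, 2, 0.8), (1, 2, 0.1)])
        top = top_degree_table(net, k=2)
        assert list(top["node"]) == ["N000", "N001"]

    def test_unknown_node_errors(self):
        net = net_from_edges([(0, 1, 0.5)])
        with pytest.raises(KeyError):
            weighted_degree(net, "missing")


class TestShortestPaths:
    def test_path_graph(self):
        net = unit_length_net([(0, 1), (1, 2)])
        dist, nxt = all_pairs_shortest_paths(net)
        assert dist[0, 2] == pytest.approx(2.0)
        assert reconstruct_path(nxt, 0, 2) == [0, 1, 2]

    def test_triangle_detour(self):
        net = net_from_edges([(0, 1, np.exp(-1)), (1, 2, np.exp(-1)),
                              (0, 2, np.exp(-3))])
        dist, _ = all_pairs_shortest_paths(net)
        assert dist[0, 2] == pytest.approx(2.0)

    def test_unreachable_is_inf(self):
        net = net_from_edges([(0, 1, 0.5)], n=3)
        dist, nxt = all_pairs_shortest_paths(net)
        assert np.isinf(dist[0, 2])
        assert reconstruct_path(nxt, 0, 2) is None

    def test_random_graphs_match_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            n = int(rng.integers(4, 13))
            net = net_from_edges(random_weighted_graph(rng, n, p=0.35), n=n)
            dist, nxt = all_pairs_shortest_paths(net)
            for s in range(n):
                for t in range(s + 1, n):
                    d_oracle, paths = enumerate_shortest(net, s, t)
                    assert dist[s, t] == pytest.approx(d_oracle)
                    rec = reconstruct_path(nxt, s, t)
                    if np.isfinite(d_oracle):
                        assert tuple(rec) in paths

    def test_triangle_inequality(self):
        rng = np.random.default_rng(3)
        net = net_from_edges(random_weighted_graph(rng, 10, p=0.5), n=10)
        dist, _ = all_pairs_shortest_paths(net)
        for i in range(10):
            for j in range(10):
                for k in range(10):
                    assert dist[i, j] <= dist[i, k] + dist[k, j] + 1e-9

    def test_matches_networkx_dijkstra(self):
        import networkx as nx

        rng = np.random.default_rng(4)
        for _ in range(30):
            n = int(rng.integers(5, 15))
            edges = random_weighted_graph(rng, n, p=0.4)
            net = net_from_edges(edges, n=n)
            G = nx.Graph()
            G.add_nodes_from(range(n))
            for i, j, c in edges:
                G.add_edge(i, j, weight=-np.log(abs(c)))
            dist, _ = all_pairs_shortest_paths(net)
            nx_dist = dict(nx.all_pairs_dijkstra_path_length(G))
            for s in range(n):
                for t in range(n):
                    expected = nx_dist[s].get(t, np.inf)
                    assert dist[s, t] == pytest.approx(expected, abs=1e-9)

    def test_removing_edge_never_shortens(self):
        rng = np.random.default_rng(5)
        edges = random_weighted_graph(rng, 8, p=0.6)
        net = net_from_edges(edges, n=8)
        dist, _ = all_pairs_shortest_paths(net)
        smaller = net.replace_edges(net.edges.iloc[1:])
        dist2, _ = all_pairs_shortest_paths(smaller)
        assert np.all(dist2 >= dist - 1e-12)


class TestEdgeBetweenness:
    def test_path_graph_counts(self):
        net = unit_length_net([(0, 1), (1, 2)])
        bt = edge_betweenness(net)
        counts = dict(zip(zip(bt["node_i"], bt["node_j"]), bt["betweenness"]))
        assert counts[(0, 1)] == 2 and counts[(1, 2)] == 2

    def test_star_spokes(self):
        net = unit_length_net([(0, i) for i in range(1, 5)])
        bt = edge_betweenness(net)
        assert (bt["betweenness"] == 4).all()  # 3 through-pairs + 1 direct

    def test_complete_graph_unit_counts(self):
        net = unit_length_net([(0, 1), (0, 2), (1, 2)])
        bt = edge_betweenness(net)
        assert (bt["betweenness"] == 1).all()

    def test_single_policy_matches_pairwise_enumeration(self):
        # distinct weights: unique shortest paths, enumeration is exact
        rng = np.random.default_rng(6)
        for _ in range(25):
            n = int(rng.integers(4, 13))
            net = net_from_edges(random_weighted_graph(rng, n, p=0.4), n=n)
            bt = edge_betweenness(net, policy="single")
            expected = np.zeros(net.n_edges)
            rows = {(int(i), int(j)): r for r, (i, j) in
                    enumerate(zip(net.edges["node_i"], net.edges["node_j"]))}
            for s in range(n):
                for t in range(s + 1, n):
                    d, paths = enumerate_shortest(net, s, t)
                    if not np.isfinite(d):
                        continue
                    assert len(paths) == 1  # distinct weights
                    (path,) = paths
                    for a, b in zip(path[:-1], path[1:]):
                        expected[rows[(min(a, b), max(a, b))]] += 1
            np.testing.assert_allclose(bt["betweenness"], expected)

    def test_fractional_matches_enumeration_and_networkx(self):
        import networkx as nx

        rng = np.random.default_rng(7)
        for trial in range(15):
            n = int(rng.integers(4, 12))
            edge_list = [(i, j) for i in range(n) for j in range(i + 1, n)
                         if rng.random() < 0.5]
            if not edge_list:
                continue
            net = unit_length_net(edge_list, n=n)  # unit lengths force ties
            bt = edge_betweenness(net, policy="fractional")
            # oracle 1: exhaustive all-shortest-paths fractional credit
            expected = np.zeros(net.n_edges)
            rows = {(int(i), int(j)): r for r, (i, j) in
                    enumerate(zip(net.edges["node_i"], net.edges["node_j"]))}
            for s in range(n):
                for t in range(s + 1, n):
                    d, paths = enumerate_shortest(net, s, t)
                    if not np.isfinite(d):
                        continue
                    for path in paths:
                        for a, b in zip(path[:-1], path[1:]):
                            expected[rows[(min(a, b), max(a, b))]] += 1 / len(paths)
            np.testing.assert_allclose(bt["betweenness"], expected, atol=1e-9)
            # oracle 2: networkx Brandes
            G = nx.Graph()
            G.add_nodes_from(range(n))
            G.add_weighted_edges_from([(i, j, 1.0) for i, j in edge_list])
            nxbc = nx.edge_betweenness_centrality(G, normalized=False,
                                                  weight="weight")
            for r, (i, j) in enumerate(zip(net.edges["node_i"],
                                           net.edges["node_j"])):
                assert bt["betweenness"][r] == pytest.approx(
                    nxbc[(int(i), int(j))], abs=1e-9)


class TestSiteStatistics:
    def test_isolated_site_zero(self):
        net = net_from_edges([(0, 1, 0.5)], n=3, chains=["A", "A", "B"])
        stats = site_path_statistics(net, ["N002"], "A")
        assert stats.count == 0

    def test_planted_bridge_found(self):
        sys_ = make_two_block_system(n_frames=3000, seed=17)
        traj = sample_trajectory(sys_)
        nm = make_node_map(traj.topology)
        C = correlation_matrix(traj, nm)
        net = build_network(C, contact_edges(traj), chains=nm.chain_ids)
        site = sys_.node_labels[sys_.site_a]      # in chain A
        stats = site_path_statistics(net, [site], "B")
        assert stats.count == 1                   # the single bridge edge
        assert {stats.edges["label_i"][0], stats.edges["label_j"][0]} == \
            {sys_.node_labels[0], sys_.node_labels[10]}

    def test_conventions_on_bipartite_toy(self):
        # complete bipartite K2,2 across chains, unit weights
        edges = [(0, 2), (0, 3), (1, 2), (1, 3)]
        net = unit_length_net(edges, chains=["A", "A", "B", "B"])
        by_paths = site_path_statistics(net, ["N000"], "B",
                                        convention="site_paths")
        assert by_paths.count == 2                # direct edges to each target
        incident = site_path_statistics(net, ["N000"], "B",
                                        convention="incident")
        assert incident.count == 4                # all cross edges near the site
        bsum = site_path_statistics(net, ["N000"], "B",
                                    convention="betweenness_sum")
        assert bsum.count == int(
            sum(by_paths.edges["betweenness"]))

    def test_unknown_site_errors(self):
        net = net_from_edges([(0, 1, 0.5)], chains=["A", "B"])
        with pytest.raises(KeyError):
            site_path_statistics(net, ["missing"], "B")


class TestSummary:
    def test_complete_graph(self):
        net = unit_length_net([(i, j) for i in range(4)
                               for j in range(i + 1, 4)])
        s = network_summary(net)
        assert s.clustering_coefficient == pytest.approx(1.0)
        assert s.degree_centralization == pytest.approx(0.0)
        assert s.mean_degree == pytest.approx(3.0)

    def test_star_graph(self):
        net = unit_length_net([(0, i) for i in range(1, 6)])
        s = network_summary(net)
        assert s.clustering_coefficient == pytest.approx(0.0)
        assert s.degree_centralization == pytest.approx(1.0)

    def test_random_graph_matches_formulas(self):
        import networkx as nx

        rng = np.random.default_rng(8)
        edges = random_weighted_graph(rng, 12, p=0.4)
        net = net_from_edges(edges, n=12)
        s = network_summary(net, degree_threshold=1.0)
        G = nx.Graph()
        G.add_nodes_from(range(12))
        G.add_edges_from([(i, j) for i, j, _ in edges])
        assert s.clustering_coefficient == pytest.approx(
            nx.average_clustering(G))
        k = np.array([G.degree(v) for v in range(12)])
        assert s.degree_centralization == pytest.approx(
            (k.max() - k).sum() / (11 * 10))
        assert s.mean_degree == pytest.approx(k.mean())
        deg = weighted_degree(net)
        assert s.n_high_degree == int((deg > 1.0).sum())

    def test_tiny_graph_centralization_flagged(self):
        net = net_from_edges([(0, 1, 0.5)])
        s = network_summary(net)
        assert s.degree_centralization is None


class TestPathway:
    def test_adjacent_nodes_single_edge(self):
        net = net_from_edges([(0, 1, 0.9)])
        p = shortest_pathway(net, "N000", "N001")
        assert p.nodes == ["N000", "N001"]
        assert p.total_length == pytest.approx(-np.log(0.9))

    def test_no_path_result(self):
        net = net_from_edges([(0, 1, 0.9)], n=3)
        p = shortest_pathway(net, "N000", "N002")
        assert not p.found

    def test_planted_pathway_recovered(self):
        sys_ = make_ring_pathway_system(n_frames=4000, seed=23)
        traj = sample_trajectory(sys_)
        nm = make_node_map(traj.topology)
        C = correlation_matrix(traj, nm)
        net = build_network(C, contact_edges(traj), chains=nm.chain_ids)
        labels = sys_.node_labels
        p = shortest_pathway(net, labels[sys_.site_a], labels[sys_.site_b])
        assert p.nodes == [labels[i] for i in sys_.pathway]
        assert p.total_length == pytest.approx(
            sum(w for _, _, w in p.edges))

    def test_insertion_order_invariance(self):
        # same graph presented in different edge/label orders gives the
        # same reported path
        edges = [(0, 1, 0.9), (1, 2, 0.9), (0, 2, 0.81), (2, 3, 0.7)]
        net1 = net_from_edges(edges)
        net2 = net_from_edges(list(reversed(edges)))
        p1 = shortest_pathway(net1, "N000", "N003")
        p2 = shortest_pathway(net2, "N000", "N003")
        assert p1.nodes == p2.nodes


class TestExport:
    def test_edge_list_and_graphml(self, tmp_path):
        import pandas as pd

        net = net_from_edges([(0, 1, 0.9), (1, 2, 0.5)],
                             chains=["A", "A", "B"])
        ep = tmp_path / "edges.tsv"
        write_edge_list(net, str(ep))
        table = pd.read_csv(ep, sep="\t")
        assert set(table.columns) == {"node_a", "node_b", "occupancy",
                                      "correlation", "length", "betweenness"}
        gp = tmp_path / "net.graphml"
        write_graphml(net, str(gp))
        import networkx as nx

        G = nx.read_graphml(str(gp))
        assert G.number_of_nodes() == 3 and G.number_of_edges() == 2
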