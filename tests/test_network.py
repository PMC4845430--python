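from itertools import combinations

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genetrends import (
    analyze,
    build_network,
    centralities,
    communities,
    giant_component,
    prune,
    summarize,
)
from genetrends.cooccurrence_network import read_edgelist, write_edgelist
from genetrends.gene_annotation import AnnotatedAbstract

from conftest import make_record


def ann(record_id, genes):
    return AnnotatedAbstract(record=make_record(record_id), genes=set(genes))


def net_of(*edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a, b, w in edges:
        g.add_edge(a, b, weight=w)
    return g


def brute_force_centralities(g):
    """All-pairs BFS with explicit shortest-path counting; independent of
    the library routines under test."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    dist, sigma = {}, {}
    for s in nodes:
        dist[s] = {s: 0}
        sigma[s] = {s: 1}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in g.neighbors(u):
                    if v not in dist[s]:
                        dist[s][v] = dist[s][u] + 1
                        sigma[s][v] = 0
                        nxt.append(v)
                    if dist[s][v] == dist[s][u] + 1:
                        sigma[s][v] += sigma[s][u]
            frontier = nxt
    betweenness = {}
    for v in nodes:
        total = 0.0
        for s, t in combinations(nodes, 2):
            if s == v or t == v or t not in dist[s]:
                continue
            if v in dist[s] and t in dist[v] and \
                    dist[s][v] + dist[v][t] == dist[s][t]:
                total += sigma[s][v] * sigma[v][t] / sigma[s][t]
        scale = (n - 1) * (n - 2) / 2
        betweenness[v] = total / scale if scale else 0.0
    closeness = {
        v: sum(1.0 / d for u, d in dist[v].items() if u != v) / (n - 1)
        if n > 1 else 0.0
        for v in nodes
    }
    return betweenness, closeness


class TestBuildNetwork:
    def test_repeated_comention_accumulates_weight(self):
        net = build_network([ann("r1", {"A", "B"}), ann("r2", {"A", "B"})])
        assert net["A"]["B"]["weight"] == 2

    def test_singleton_gene_is_a_node_without_edges(self):
        net = build_network([ann("r1", {"A"})])
        assert set(net.nodes) == {"A"} and net.number_of_edges() == 0

    def test_triple_mention_gives_three_unit_edges(self):
        net = build_network([ann("r1", {"A", "B", "C"})])
        assert net.number_of_edges() == 3  # C(3,2)
        assert all(w == 1 for _, _, w in net.edges(data="weight"))

    def test_weight_identity_sum_over_records(self):
        records = [ann("r1", {"A", "B", "C"}), ann("r2", {"A", "B"}),
                   ann("r3", {"C"})]
        net = build_network(records)
        total = sum(w for _, _, w in net.edges(data="weight"))
        expected = sum(
            len(a.genes) * (len(a.genes) - 1) // 2 for a in records
        )
        assert total == expected


class TestGiantComponent:
    def test_largest_component_wins(self):
        net = net_of(("a", "b", 1), ("b", "c", 1), ("c", "d", 1), ("d", "e", 1),
                     ("x", "y", 1))
        assert set(giant_component(net).nodes) == {"a", "b", "c", "d", "e"}

    def test_connected_net_is_identity(self):
        net = net_of(("a", "b", 1), ("b", "c", 1))
        assert set(giant_component(net).nodes) == set(net.nodes)

    def test_isolated_nodes_lose_to_any_edge(self):
        net = net_of(("x", "y", 1), nodes=["i1", "i2", "i3"])
        assert set(giant_component(net).nodes) == {"x", "y"}

    def test_empty_net_rejected(self):
        with pytest.raises(ValueError):
            giant_component(nx.Graph())


class TestPrune:
    def test_boundary_keeps_weight_equal_to_threshold(self):
        net = net_of(("a", "b", 9), ("c", "d", 10))
        pruned = prune(net, 10)
        assert set(pruned.nodes) == {"c", "d"}
        assert pruned.has_edge("c", "d")

    def test_min_weight_one_keeps_all_connected_nodes(self):
        net = net_of(("a", "b", 1), nodes=["solo"])
        pruned = prune(net, 1)
        assert set(pruned.nodes) == {"a", "b"}

    def test_all_below_threshold_empties_network(self):
        assert prune(net_of(("a", "b", 3)), 10).number_of_nodes() == 0

    def test_prune_composition_equals_max_threshold(self):
        net = net_of(("a", "b", 3), ("b", "c", 7), ("c", "d", 12), ("d", "e", 5))
        twice = prune(prune(net, 5), 10)
        once = prune(net, 10)
        assert nx.utils.graphs_equal(twice, once)


class TestCentralities:
    def test_path_middle_node_has_full_centrality(self):
        # brute force on A-B-C: B sits on the only indirect shortest path
        b, c = centralities(net_of(("A", "B", 1), ("B", "C", 1)))
        assert b["B"] == pytest.approx(1.0)
        assert b["A"] == b["C"] == 0.0
        assert c["B"] == pytest.approx(1.0)
        assert c["A"] == pytest.approx((1 + 0.5) / 2)

    def test_star_center_one_leaves_zero(self):
        edges = [("hub", f"l{i}", 1) for i in range(5)]
        b, _ = centralities(net_of(*edges))
        assert b["hub"] == pytest.approx(1.0)
        assert all(b[f"l{i}"] == 0.0 for i in range(5))

    def test_complete_graph_all_betweenness_zero(self):
        g = net_of(*[(a, b, 1) for a, b in combinations("abcd", 2)])
        b, c = centralities(g)
        assert all(v == 0.0 for v in b.values())
        assert all(v == pytest.approx(1.0) for v in c.values())

    def test_single_node_both_zero(self):
        b, c = centralities(net_of(nodes=["only"]))
        assert b == {"only": 0.0} and c == {"only": 0.0}

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(2, 12), st.floats(0.15, 0.8), st.integers(0, 10**6))
    def test_oracle_equivalence_on_random_graphs(self, n, p, graph_seed):
        g = nx.gnp_random_graph(n, p, seed=graph_seed)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        got_b, got_c = centralities(g)
        exp_b, exp_c = brute_force_centralities(g)
        for v in g.nodes:
            assert got_b[v] == pytest.approx(exp_b[v], abs=1e-9)
            assert got_c[v] == pytest.approx(exp_c[v], abs=1e-9)
        assert all(0.0 <= got_b[v] <= 1.0 for v in g.nodes)
        assert all(0.0 <= got_c[v] <= 1.0 for v in g.nodes)


class TestCommunities:
    def test_two_cliques_with_bridge_split_into_cliques(self):
        # exhaustive partition search over 8 nodes confirms the two 4-cliques
        # are the modularity optimum for this graph
        g = nx.Graph()
        left, right = ["a1", "a2", "a3", "a4"], ["b1", "b2", "b3", "b4"]
        g.add_edges_from((u, v, {"weight": 1}) for u, v in combinations(left, 2))
        g.add_edges_from((u, v, {"weight": 1}) for u, v in combinations(right, 2))
        g.add_edge("a1", "b1", weight=1)
        labels, score = communities(g, seed=3)
        assert len({labels[v] for v in left}) == 1
        assert len({labels[v] for v in right}) == 1
        assert labels["a1"] != labels["b1"]
        assert score > 0.3

    def test_single_clique_one_community(self):
        g = net_of(*[(a, b, 1) for a, b in combinations("abcd", 2)])
        labels, _ = communities(g, seed=1)
        assert len(set(labels.values())) == 1

    def test_same_seed_identical_labels(self):
        g = nx.les_miserables_graph()
        assert communities(g, seed=9) == communities(g, seed=9)

    def test_edgeless_network_singleton_classes_score_zero(self):
        labels, score = communities(net_of(nodes=["a", "b"]), seed=0)
        assert labels == {"a": 0, "b": 1} and score == 0.0

    def test_labels_contiguous_from_zero(self):
        g = nx.les_miserables_graph()
        labels, _ = communities(g, seed=5)
        assert set(labels.values()) == set(range(len(set(labels.values()))))


class TestSummarize:
    def test_percentages_recomputed_to_two_decimals(self):
        full = nx.empty_graph(0, create_using=nx.Graph)
        # 90.71 % of 8400 nodes is 7620: check the arithmetic on small
        # numbers with the same ratio structure
        full = net_of(*[(f"a{i}", f"b{i}", 1) for i in range(10)])
        giant = full.subgraph([n for n in full.nodes][:18]).copy()
        pruned = giant.copy()
        table = summarize(full, giant, pruned).set_index("stage")
        assert table.loc["full", "node_pct"] == 100.0
        assert table.loc["giant", "node_pct"] == 90.0
        assert table.loc["giant", "nodes"] == 18

    def test_inconsistent_stages_rejected(self):
        full = net_of(("a", "b", 1))
        rogue = net_of(("x", "y", 1))
        with pytest.raises(ValueError):
            summarize(full, rogue, rogue)

    def test_identical_stages_all_100(self):
        g = net_of(("a", "b", 1))
        table = summarize(g, g, g)
        assert (table["node_pct"] == 100.0).all()
        assert (table["edge_pct"] == 100.0).all()


class TestEdgelistIO:
    def test_round_trip(self, tmp_path):
        net = net_of(("a", "b", 3), ("b", "c", 11))
        path = tmp_path / "edges.tsv"
        write_edgelist(net, path)
        again = read_edgelist(path)
        assert nx.utils.graphs_equal(net, again)


class TestPlantedCommunityRecovery:
    def test_louvain_recovers_planted_blocks(self, default_synthetic):
        """Three planted 15-gene co-mention blocks with p_in = 0.6 and
        p_out = 0.02 must be recovered exactly on the pruned network."""
        from sklearn.metrics import adjusted_rand_score

        spec, _, truth, annotated = default_synthetic
        pruned = prune(giant_component(build_network(annotated)), 10)
        result = analyze(pruned, seed=11)
        genes = [g for g in pruned.nodes if g in truth.community_of]
        assert len(genes) == len(spec.community_genes)
        ari = adjusted_rand_score(
            [truth.community_of[g] for g in genes],
            [result.modularity_class[g] for g in genes],
        )
        assert ari >= 0.9
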