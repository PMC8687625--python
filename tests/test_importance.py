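"""Nim score, baseline centralities, FRS thresholding and subtype labels."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cfig.errors import ValidationError
from cfig.importance import (
    NimTable,
    assign_communities,
    baseline_centrality,
    classify_key_proteins,
    compute_nim,
    compute_uet,
    frs_threshold,
    select_frs,
)
from cfig.networks import WeightedNetwork

from oracles import brute_betweenness, brute_nim


def wrap(G: nx.Graph) -> WeightedNetwork:
    net = WeightedNetwork()
    for n in G.nodes:
        net.add_node(str(n), "gene")
    for a, b in G.edges:
        net.add_edge(str(a), str(b))
    return net


class TestCommunities:
    def test_connected_graph_is_one_community(self):
        net = wrap(nx.path_graph(4))
        comm = assign_communities(net)
        assert len(set(comm.membership.values())) == 1

    def test_two_triangles_two_communities(self):
        G = nx.Graph([(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)])
        comm = assign_communities(wrap(G))
        groups = comm.communities()
        assert sorted(len(v) for v in groups.values()) == [3, 3]

    def test_modularity_mode_is_seeded_deterministic(self):
        G = nx.gnp_random_graph(30, 0.15, seed=5)
        net = wrap(G)
        a = assign_communities(net, "modularity", seed=11).membership
        b = assign_communities(net, "modularity", seed=11).membership
        assert a == b


class TestNim:
    def test_path_center_scores_four(self):
        net = wrap(nx.path_graph(3))
        table = compute_nim(net, assign_communities(net))
        assert table.nim == {"0": 0.0, "1": 4.0, "2": 0.0}

    def test_star_leaves_score_zero_center_96(self):
        net = wrap(nx.star_graph(4))  # center "0", four leaves
        table = compute_nim(net, assign_communities(net))
        assert table.nim["0"] == pytest.approx(96.0)
        assert all(table.nim[str(k)] == 0.0 for k in range(1, 5))
        assert table.betweenness_term["0"] == pytest.approx(6.0)

    def test_leaf_of_k13_scores_zero(self):
        net = wrap(nx.star_graph(3))
        table = compute_nim(net, assign_communities(net))
        assert table.nim["1"] == 0.0

    def test_matches_brute_force_nim_on_random_graphs(self):
        rng = np.random.default_rng(3)
        for _ in range(15):
            G = nx.gnp_random_graph(8, rng.uniform(0.2, 0.6), seed=int(rng.integers(1 << 30)))
            net = wrap(G)
            comm = assign_communities(net)
            table = compute_nim(net, comm)
            expected = brute_nim(list(net.nodes), set(map(tuple, net.edges)),
                                 dict(comm.membership))
            for n in net.nodes:
                assert table.nim[n] == pytest.approx(expected[n], abs=1e-9)

    def test_singleton_community_factor_is_zero(self):
        G = nx.Graph()
        G.add_nodes_from([0, 1, 2])
        G.add_edge(0, 1)
        net = wrap(G)
        table = compute_nim(net, assign_communities(net))
        assert table.community_factor["2"] == 0.0

    def test_missing_community_raises(self):
        net = wrap(nx.path_graph(3))
        from cfig.importance import CommunityAssignment

        with pytest.raises(ValidationError):
            compute_nim(net, CommunityAssignment({"0": 0, "1": 0}, "partial"))

    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariant_under_relabeling(self, seed):
        G = nx.gnp_random_graph(7, 0.4, seed=seed % 997)
        net = wrap(G)
        table = compute_nim(net, assign_communities(net))
        mapping = {n: f"X{(int(n) * 7 + 3) % 97:02d}" for n in net.nodes}
        H = nx.relabel_nodes(net.graph, mapping)
        net2 = wrap(H)
        table2 = compute_nim(net2, assign_communities(net2))
        for n in net.nodes:
            assert table2.nim[mapping[n]] == pytest.approx(table.nim[n])


class TestBaselines:
    def test_triangle_degree_and_clustering(self):
        net = wrap(nx.complete_graph(3))
        assert set(baseline_centrality(net, "degree").values()) == {2.0}
        assert set(baseline_centrality(net, "clustering_coefficient").values()) == {1.0}

    def test_path_center_closeness_is_one(self):
        net = wrap(nx.path_graph(3))
        assert baseline_centrality(net, "closeness")["1"] == pytest.approx(1.0)

    def test_degree_matches_exhaustive_count(self):
        G = nx.gnp_random_graph(12, 0.3, seed=2)
        net = wrap(G)
        deg = baseline_centrality(net, "degree")
        for n in net.nodes:
            assert deg[n] == sum(1 for e in net.edges if n in e)


class TestFrs:
    def _table(self, scores):
        return NimTable({k: 0.0 for k in scores}, {k: 0.0 for k in scores},
                        dict(scores))

    def test_midpoint_rule(self):
        t = self._table({"a": 1, "b": 2, "c": 3, "d": 10})
        res = select_frs(t, "midpoint")
        assert res.threshold_value == 5.5
        assert res.kept == {"d"}

    def test_mean_rule(self):
        t = self._table({"a": 1, "b": 2, "c": 3, "d": 10})
        res = select_frs(t, "mean")
        assert res.threshold_value == 4.0
        assert res.kept == {"d"}

    def test_all_equal_scores_keep_everything(self):
        t = self._table({"a": 2.0, "b": 2.0, "c": 2.0})
        for mode in ("midpoint", "mean", "median"):
            assert select_frs(t, mode).kept == {"a", "b", "c"}

    @given(st.dictionaries(st.text("abcdefgh", min_size=1, max_size=3),
                           st.floats(min_value=0, max_value=1e6, allow_nan=False),
                           min_size=1, max_size=20))
    def test_every_mode_keeps_at_least_one_node(self, scores):
        t = self._table(scores)
        for mode in ("midpoint", "mean", "median"):
            assert len(select_frs(t, mode).kept) >= 1

    def test_threshold_errors_on_empty(self):
        with pytest.raises(ValidationError):
            frs_threshold({}, "midpoint")


class TestSubtypesAndUet:
    def test_three_way_partition(self):
        subtypes, warns = classify_key_proteins(
            {"A", "B", "C"}, disease_genes={"A", "B"}, target_genes={"A", "C"})
        assert subtypes == {"A": "essential_common",
                            "B": "disease_specific",
                            "C": "ingredient_specific"}
        assert warns == []

    def test_uet_is_plain_intersection(self):
        assert compute_uet({"A", "B"}, {"B", "C"}) == {"B"}
        assert compute_uet({"A"}, {"A"}) == {"A"}
        assert compute_uet({"A"}, {"B"}) == set()

    def test_uet_on_study_matches_set_oracle(self, study7):
        disease = {e.gene for e in study7.evidence}
        targets = {g for _, g in study7.associations}
        assert compute_uet(disease, targets) == disease & targets

    def test_uet_empty_inputs_raise(self):
        with pytest.raises(ValidationError):
            compute_uet(set(), {"A"})


class TestBetweennessTermOracle:
    def test_small_random_graphs_match_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            G = nx.gnp_random_graph(7, 0.35, seed=int(rng.integers(1 << 30)))
            net = wrap(G)
            table = compute_nim(net, assign_communities(net))
            brute = brute_betweenness(list(net.nodes), set(map(tuple, net.edges)))
            for n in net.nodes:
                assert table.betweenness_term[n] == pytest.approx(brute[n], abs=1e-9)
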