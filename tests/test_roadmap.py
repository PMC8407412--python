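import itertools

import networkx as nx
import numpy as np
import pytest

from transitnet import (
    build_network,
    habitat_roadmap,
    roadmap_significance,
    sample_mst,
    transitive_closures,
)
from transitnet.network import TransitionNetwork


def weighted_net(edges, habitats=None):
    g = nx.Graph()
    for a, b, s in edges:
        g.add_edge(a, b, similarity=s)
    return TransitionNetwork(graph=g, T_dt=0.0, k=100,
                             measure_name="braycurtis",
                             habitat=habitats or {})


def brute_force_min_spanning_total(graph):
    """Exhaustive minimum over all spanning trees (<= 7 nodes)."""
    nodes = list(graph.nodes)
    edges = [(a, b, 1.0 - d["similarity"])
             for a, b, d in graph.edges(data=True)]
    best = None
    for combo in itertools.combinations(edges, len(nodes) - 1):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from((a, b) for a, b, _ in combo)
        if nx.is_connected(g):
            total = sum(d for _, _, d in combo)
            best = total if best is None else min(best, total)
    return best


class TestSampleMst:
    def test_triangle_drops_largest_distance(self):
        net = weighted_net([("a", "b", 0.99), ("b", "c", 0.95),
                            ("a", "c", 0.90)])
        mst = sample_mst(net)
        kept = {(a, b) for a, b, _ in mst.edges}
        assert kept == {("a", "b"), ("b", "c")}
        assert mst.total_distance == pytest.approx(0.06)

    def test_tree_network_is_its_own_mst(self):
        net = weighted_net([("a", "b", 0.9), ("b", "c", 0.8),
                            ("c", "d", 0.95)])
        mst = sample_mst(net)
        assert len(mst.edges) == 3
        assert mst.total_distance == pytest.approx(0.1 + 0.2 + 0.05)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(9)
        nodes = [f"n{i}" for i in range(6)]
        edges = [(a, b, float(rng.uniform(0.5, 1.0)))
                 for a, b in itertools.combinations(nodes, 2)
                 if rng.uniform() < 0.7]
        net = weighted_net(edges)
        if not nx.is_connected(net.graph):
            pytest.skip("random fixture disconnected")
        mst = sample_mst(net)
        assert mst.total_distance == pytest.approx(
            brute_force_min_spanning_total(net.graph))

    def test_disconnected_closure_rejected(self):
        net = weighted_net([("a", "b", 0.9), ("c", "d", 0.9)])
        with pytest.raises(ValueError, match="disconnected"):
            sample_mst(net)

    def test_deterministic_under_ties(self):
        net = weighted_net([("a", "b", 0.9), ("b", "c", 0.9),
                            ("a", "c", 0.9)])
        mst = sample_mst(net)
        assert {(a, b) for a, b, _ in mst.edges} == \
            {("a", "b"), ("a", "c")}


class TestHabitatRoadmap:
    def test_mean_of_supporting_edges(self):
        net = weighted_net([("a1", "a2", 0.99), ("a1", "b1", 0.90),
                            ("a2", "b2", 0.80), ("b1", "b2", 0.99)])
        hab = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        mst = sample_mst(net)
        rm = habitat_roadmap(mst, hab)
        [(ha, hb, dist, n)] = rm.edges
        assert (ha, hb) == ("A", "B")
        # the MST keeps only the cheaper inter-habitat edge (0.10)
        assert dist == pytest.approx(0.10) and n == 1

    def test_mean_over_multiple_support_edges(self):
        # force both inter-habitat edges into the MST: no within-B edge
        net = weighted_net([("a1", "a2", 0.99), ("a1", "b1", 0.90),
                            ("a2", "b2", 0.80)])
        hab = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        rm = habitat_roadmap(sample_mst(net), hab)
        [(_, _, dist, n)] = rm.edges
        assert n == 2 and dist == pytest.approx((0.10 + 0.20) / 2)

    def test_three_habitat_triangle_keeps_two_cheapest(self):
        net = weighted_net([
            ("a1", "b1", 0.9), ("b1", "c1", 0.8), ("a2", "c1", 0.7),
            ("a1", "a2", 0.99),
        ])
        hab = {"a1": "A", "a2": "A", "b1": "B", "c1": "C"}
        rm = habitat_roadmap(sample_mst(net), hab)
        kept = {(a, b) for a, b, _, _ in rm.edges}
        assert kept == {("A", "B"), ("B", "C")}

    def test_edge_count_matches_component_count(self, chained_dataset):
        net = build_network(chained_dataset, "braycurtis", T_dt=0.7, k=100)
        mst = sample_mst(net, transitive_closures(net)[0])
        rm = habitat_roadmap(mst, chained_dataset.habitat)
        assert len(rm.edges) == len(rm.habitats) - rm.n_components

    def test_single_habitat_rejected(self):
        net = weighted_net([("a1", "a2", 0.9)])
        with pytest.raises(ValueError, match="2 habitats"):
            habitat_roadmap(sample_mst(net), {"a1": "A", "a2": "A"})


class TestRoadmapSignificance:
    def chain_net(self):
        """A-B-C chain with 16 parallel candidate edges per habitat pair."""
        rng = np.random.default_rng(2)
        edges, hab = [], {}
        for h in "abc":
            for i in range(4):
                hab[f"{h}{i}"] = h.upper()
            for i in range(3):
                edges.append((f"{h}{i}", f"{h}{i + 1}", 0.99))
        for ha, hb in (("a", "b"), ("b", "c")):
            sims = rng.uniform(0.87, 0.97, size=16)
            for n, s in enumerate(sims):
                edges.append((f"{ha}{n // 4}", f"{hb}{n % 4}", float(s)))
        return weighted_net(edges, hab)

    def test_degenerate_null_gives_p_one(self):
        net = weighted_net(
            [("a1", "b1", 0.9), ("a1", "b2", 0.9), ("a2", "b1", 0.9),
             ("a1", "a2", 0.99), ("b1", "b2", 0.99)],
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        rm = habitat_roadmap(sample_mst(net), net.habitat)
        p = roadmap_significance(rm, net, n_perm=100, seed=0)
        assert p == 1.0

    def test_minimal_roadmap_approaches_permutation_floor(self):
        net = self.chain_net()
        rm = habitat_roadmap(sample_mst(net), net.habitat)
        p = roadmap_significance(rm, net, n_perm=10_000, seed=1)
        # the MST picks the cheapest inter-habitat edges, so only the
        # rare permutation drawing those same minima can tie it
        assert p < 0.01

    def test_same_seed_same_p(self):
        net = self.chain_net()
        rm = habitat_roadmap(sample_mst(net), net.habitat)
        assert roadmap_significance(rm, net, n_perm=500, seed=9) == \
            roadmap_significance(rm, net, n_perm=500, seed=9)

    def test_missing_candidate_pool_rejected(self):
        net = weighted_net([("a1", "b1", 0.9)],
                           {"a1": "A", "b1": "B"})
        rm = habitat_roadmap(sample_mst(net), net.habitat)
        # erase the only candidate edge's habitat labels consistency
        net.graph.remove_edge("a1", "b1")
        with pytest.raises(ValueError, match="no network edges"):
            roadmap_significance(rm, net, n_perm=10, seed=0)


class TestChainRecovery:
    def test_planted_habitat_chain_recovered(self, chained_dataset):
        net = build_network(chained_dataset, "braycurtis", T_dt=0.7, k=100)
        mst = sample_mst(net, transitive_closures(net)[0])
        rm = habitat_roadmap(mst, chained_dataset.habitat)
        assert {(a, b) for a, b, _, _ in rm.edges} == \
            {("H1", "H2"), ("H2", "H3")}
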