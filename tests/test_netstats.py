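import itertools

import networkx as nx
import numpy as np
import pytest

from transitnet import (
    build_network,
    degree_histogram,
    robustness_experiment,
    scalefree_fit,
    step_stats,
    transition_frequencies,
    transitive_closures,
)

from test_closures import net_from_edges


class TestStepStats:
    def test_path_graph(self):
        net = net_from_edges([("a", "b"), ("b", "c")])
        st = step_stats(net)
        assert st.mean_steps == pytest.approx(4 / 3)
        assert st.diameter == 2
        assert st.histogram == {1: 2, 2: 1}

    def test_complete_graph(self):
        edges = list(itertools.combinations("abcd", 2))
        st = step_stats(net_from_edges(edges))
        assert st.mean_steps == 1.0 and st.diameter == 1

    def test_star_graph(self):
        net = net_from_edges([("h", "a"), ("h", "b"), ("h", "c")])
        st = step_stats(net)
        # 3 pairs at distance 1 (hub-leaf), 3 at distance 2
        assert st.mean_steps == pytest.approx(1.5)
        assert st.diameter == 2

    def test_single_node_closure_rejected(self):
        net = net_from_edges([], nodes=["a"])
        with pytest.raises(ValueError):
            step_stats(net, {"a"})

    def test_matches_floyd_warshall_oracle(self, random_set):
        net = build_network(random_set, "braycurtis", T_dt=0.7, k=100)
        main = transitive_closures(net)[0]
        st = step_stats(net, main)
        fw = dict(nx.floyd_warshall(net.graph.subgraph(main.members),
                                    weight=None))
        dists = [int(fw[a][b]) for a, b in
                 itertools.combinations(sorted(main.members), 2)]
        assert st.n_pairs == len(dists)
        assert st.mean_steps == pytest.approx(np.mean(dists))
        assert st.diameter == max(dists)
        hist = {}
        for d in dists:
            hist[d] = hist.get(d, 0) + 1
        assert st.histogram == hist

    def test_sampled_pairs_flagged_and_seeded(self, random_set):
        net = build_network(random_set, "braycurtis", T_dt=0.7, k=100)
        main = transitive_closures(net)[0]
        a = step_stats(net, main, max_pairs=10, seed=4)
        b = step_stats(net, main, max_pairs=10, seed=4)
        assert a == b
        assert a.sampled and not a.diameter_exact and a.n_pairs == 10


class TestDegreeHistogram:
    @pytest.mark.parametrize(
        "edges,nodes,expected",
        [
            ([("a", "b"), ("b", "c"), ("a", "c")], (), {2: 3}),
            ([], "abc", {0: 3}),
            ([("h", "a"), ("h", "b"), ("h", "c")], (), {1: 3, 3: 1}),
        ],
    )
    def test_small_graphs(self, edges, nodes, expected):
        assert degree_histogram(net_from_edges(edges, nodes)) == expected

    def test_handshake_lemma(self, random_set):
        net = build_network(random_set, "braycurtis", T_dt=0.7, k=100)
        hist = degree_histogram(net)
        assert sum(k * c for k, c in hist.items()) == 2 * net.n_edges


class TestScalefreeFit:
    def test_exact_power_law(self):
        # counts proportional to k^-2 over k in {1,2,4,8}
        fit = scalefree_fit({1: 64, 2: 16, 4: 4, 8: 1})
        assert fit.pearson_r == pytest.approx(-1.0, abs=1e-9)
        assert fit.slope == pytest.approx(-2.0, abs=1e-9)

    def test_flat_distribution_gives_zero_r(self):
        fit = scalefree_fit({1: 10, 2: 10, 4: 10})
        assert fit.slope == pytest.approx(0.0)
        assert fit.pearson_r == 0.0

    def test_degree_zero_excluded_from_fit(self):
        with_zero = scalefree_fit({0: 99, 1: 64, 2: 16, 4: 4, 8: 1})
        without = scalefree_fit({1: 64, 2: 16, 4: 4, 8: 1})
        assert with_zero.pearson_r == without.pearson_r
        assert with_zero.slope == without.slope
        assert 0 not in with_zero.histogram

    def test_insufficient_diversity_rejected(self):
        with pytest.raises(ValueError, match="insufficient degree diversity"):
            scalefree_fit({1: 5, 2: 3})


class TestRobustness:
    def test_full_retention_equals_baseline(self, random_set):
        net = build_network(random_set, "braycurtis", T_dt=0.7, k=100)
        from transitnet import main_closure_fraction

        rob = robustness_experiment(net, fractions=[1.0], reps=2, seed=0)
        np.testing.assert_allclose(rob["main_closure_fraction"],
                                   main_closure_fraction(net))

    def test_complete_graph_never_fragments(self):
        edges = list(itertools.combinations([f"n{i}" for i in range(20)], 2))
        net = net_from_edges(edges)
        rob = robustness_experiment(net, fractions=[0.25, 0.5, 0.75],
                                    reps=3, seed=1)
        assert (rob["main_closure_fraction"] == 1.0).all()

    def test_same_seed_reproduces_table(self, random_set):
        net = build_network(random_set, "braycurtis", T_dt=0.7, k=100)
        a = robustness_experiment(net, fractions=[0.5, 0.9], reps=3, seed=7)
        b = robustness_experiment(net, fractions=[0.5, 0.9], reps=3, seed=7)
        assert a.equals(b)

    def test_connectivity_trend_improves_with_retention(self, chained_dataset):
        net = build_network(chained_dataset, "braycurtis", T_dt=0.7, k=100)
        rob = robustness_experiment(net, fractions=[0.3, 0.9], reps=10, seed=2)
        means = rob.groupby("retain_fraction")["main_closure_fraction"].mean()
        assert means[0.9] >= means[0.3]


class TestTransitionFrequencies:
    def test_single_habitat_triangle(self):
        net = net_from_edges([("a", "b"), ("b", "c"), ("a", "c")])
        tf = transition_frequencies(net, {"a": "gut", "b": "gut", "c": "gut"})
        # 3 within edges, each counted for both endpoints, over 3 samples
        assert tf.within == {"gut": 2.0}
        assert tf.between == {"gut": 0.0}

    def test_bipartite_pair(self):
        net = net_from_edges([("a", "b")])
        tf = transition_frequencies(net, {"a": "gut", "b": "soil"})
        assert tf.within == {"gut": 0.0, "soil": 0.0}
        assert tf.between == {"gut": 1.0, "soil": 1.0}

    def test_empty_network_all_zero(self):
        net = net_from_edges([], nodes=["a", "b"])
        tf = transition_frequencies(net, {"a": "gut", "b": "soil"})
        assert all(v == 0.0 for v in tf.within.values())
        assert all(v == 0.0 for v in tf.between.values())

    def test_mock_samples_excluded(self):
        net = net_from_edges([("a", "m"), ("a", "b")])
        tf = transition_frequencies(
            net, {"a": "gut", "b": "gut", "m": "mock"})
        assert "mock" not in tf.within
        assert tf.within == {"gut": 2 * 1 / 2}

    def test_within_exceeds_between_on_habitat_structured_data(
            self, habitat_dataset):
        net = build_network(habitat_dataset, "braycurtis", T_dt=0.7, k=100)
        tf = transition_frequencies(net)
        assert all(tf.within[h] > tf.between[h] for h in tf.within)
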