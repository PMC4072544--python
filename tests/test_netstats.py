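"""Network metrics, node-class selection and group statistics."""

import itertools

import networkx as nx
import numpy as np
import pytest

from ncrates.netstats import (
    NetworkMetrics,
    compute_metrics,
    group_tests,
    rewired_consensus,
    select_bottlenecks,
    select_hubs,
    smd,
)
from ncrates.simulate import synthetic_network_pair


def star(n_leaves=4):
    return [("hub", f"leaf{i}") for i in range(n_leaves)]


def brute_force_betweenness(g):
    """Independent betweenness oracle: enumerate all shortest paths."""
    out = {n: 0.0 for n in g}
    for s, t in itertools.combinations(list(g), 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for path in paths:
            for node in path[1:-1]:
                out[node] += 1.0 / len(paths)
    return out


class TestComputeMetrics:
    def test_star_graph_hand_values(self):
        metrics = compute_metrics(star())
        assert metrics.degree["hub"] == 4
        assert all(metrics.degree[f"leaf{i}"] == 1 for i in range(4))
        assert metrics.betweenness["hub"] == pytest.approx(6.0)  # C(4,2) leaf pairs

    def test_path_graph_hand_values(self):
        metrics = compute_metrics([("a", "b"), ("b", "c")])
        assert metrics.betweenness["b"] == pytest.approx(1.0)
        assert metrics.betweenness["a"] == metrics.betweenness["c"] == 0.0

    def test_betweenness_matches_exhaustive_oracle_on_random_graphs(self):
        rng = np.random.default_rng(12)
        for trial in range(6):
            g = nx.gnp_random_graph(10, 0.3, seed=int(rng.integers(1e6)))
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g})
            if g.number_of_edges() == 0:
                continue
            metrics = compute_metrics(list(g.edges()))
            expected = brute_force_betweenness(g)
            for node, value in expected.items():
                if g.degree(node) == 0:
                    continue  # isolated nodes never enter the edge list
                assert metrics.betweenness.get(node, 0.0) == pytest.approx(value)

    def test_self_loops_and_duplicates_collapsed(self):
        metrics = compute_metrics([("a", "b"), ("a", "b"), ("a", "a")])
        assert metrics.degree == {"a": 1, "b": 1}

    def test_full_ortholog_map_zeroes_nonortholog_counts(self):
        edges = star()
        orth = {n: n.upper() for n in ["hub"] + [f"leaf{i}" for i in range(4)]}
        metrics = compute_metrics(edges, ortholog_map=orth)
        assert all(v == 0 for v in metrics.nonortholog_neighbors.values())

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_metrics([])


class TestHubSelection:
    def test_degree_ladder_top_decile(self):
        metrics = NetworkMetrics(
            degree={f"n{i}": i for i in range(1, 101)},
            betweenness={f"n{i}": 0.0 for i in range(1, 101)},
        )
        hubs, non_hubs, degenerate = select_hubs(metrics)
        assert hubs == {f"n{i}" for i in range(91, 101)}
        assert non_hubs == {f"n{i}" for i in range(1, 11)}
        assert not degenerate

    def test_all_equal_degrees_flagged_degenerate(self):
        metrics = NetworkMetrics(
            degree={f"n{i}": 3 for i in range(20)},
            betweenness={f"n{i}": 0.0 for i in range(20)},
        )
        _, _, degenerate = select_hubs(metrics)
        assert degenerate

    def test_selection_invariant_to_relabeling(self):
        rng = np.random.default_rng(3)
        degrees = {f"n{i}": int(rng.integers(1, 50)) for i in range(40)}
        metrics = NetworkMetrics(degree=degrees, betweenness=dict.fromkeys(degrees, 0.0))
        hubs, _, _ = select_hubs(metrics)
        relabeled = NetworkMetrics(
            degree={"x" + k: v for k, v in degrees.items()},
            betweenness={"x" + k: 0.0 for k in degrees},
        )
        hubs2, _, _ = select_hubs(relabeled)
        assert {"x" + h for h in hubs} == hubs2


class TestBottleneckSelection:
    def test_star_center_is_hub_not_bottleneck(self):
        edges = star(12)
        metrics = compute_metrics(edges)
        hubs, _, _ = select_hubs(metrics)
        bottlenecks, _, _ = select_bottlenecks(metrics, hubs)
        assert "hub" in hubs
        assert "hub" not in bottlenecks

    def test_bridge_between_cliques_is_bottleneck(self):
        # two 5-cliques joined through a low-degree bridge node
        edges = [(f"a{i}", f"a{j}") for i in range(5) for j in range(i + 1, 5)]
        edges += [(f"b{i}", f"b{j}") for i in range(5) for j in range(i + 1, 5)]
        edges += [("a0", "bridge"), ("bridge", "b0")]
        metrics = compute_metrics(edges)
        hubs, _, _ = select_hubs(metrics)
        bottlenecks, _, _ = select_bottlenecks(metrics, hubs)
        assert "bridge" in bottlenecks

    def test_bottlenecks_always_disjoint_from_hubs(self):
        g = nx.gnp_random_graph(40, 0.15, seed=5)
        metrics = compute_metrics([(str(u), str(v)) for u, v in g.edges()])
        hubs, _, _ = select_hubs(metrics)
        bottlenecks, _, _ = select_bottlenecks(metrics, hubs)
        assert not bottlenecks & hubs


class TestRewiredConsensus:
    def test_no_nonortholog_edges_gives_empty_consensus(self):
        edges_a, edges_b, orth, _ = synthetic_network_pair(
            n_nodes=40, ortholog_fraction=1.0, n_planted_rewired=0,
            extra_nonortholog_edges=0, seed=21,
        )
        reverse = {b: a for a, b in orth.items()}
        ma = compute_metrics(edges_a, ortholog_map=orth)
        mb = compute_metrics(edges_b, ortholog_map=reverse)
        assert rewired_consensus(ma, mb, orth) == set()

    def test_planted_nodes_recovered(self):
        recovered = total = 0
        for seed in range(5):
            edges_a, edges_b, orth, planted = synthetic_network_pair(
                n_nodes=200, n_planted_rewired=5, seed=seed
            )
            reverse = {b: a for a, b in orth.items()}
            ma = compute_metrics(edges_a, ortholog_map=orth)
            mb = compute_metrics(edges_b, ortholog_map=reverse)
            consensus = rewired_consensus(ma, mb, orth)
            recovered += len(consensus & set(planted))
            total += len(planted)
        assert recovered / total >= 0.9


class TestGroupStatistics:
    def test_smd_identical_samples_is_zero(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert smd(x, list(x)) == 0.0

    def test_smd_recovers_one_sd_shift(self):
        rng = np.random.default_rng(17)
        x = rng.normal(1.0, 1.0, 20000)
        y = rng.normal(0.0, 1.0, 20000)
        assert smd(x, y) == pytest.approx(1.0, abs=0.05)

    def test_smd_antisymmetric_and_scale_invariant(self):
        rng = np.random.default_rng(18)
        x = list(rng.normal(0.4, 1.2, 50))
        y = list(rng.normal(0.0, 0.8, 60))
        assert smd(x, y) == pytest.approx(-smd(y, x))
        assert smd([3 * v for v in x], [3 * v for v in y]) == pytest.approx(smd(x, y))

    def test_wilcoxon_on_constant_equal_samples_gives_p_one(self):
        result = group_tests([5.0] * 10, [5.0] * 10)
        assert result.p_value == pytest.approx(1.0)
        assert result.smd == 0.0

    def test_fisher_on_perfectly_separated_table(self):
        result = group_tests(table=[[10, 0], [0, 10]])
        assert result.statistic_name == "fisher_exact"
        assert result.p_value < 1e-3

    def test_wilcoxon_type_one_error_calibration(self):
        rng = np.random.default_rng(19)
        rejections = 0
        n_sims = 400
        for _ in range(n_sims):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            if group_tests(x, y).p_value < 0.05 :
                rejections += 1
        rate = rejections / n_sims
        # binomial 99.9% envelope around 0.05 for 400 simulations
        assert 0.01 < rate < 0.10

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            group_tests([], [1.0])
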