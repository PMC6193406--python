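import math
import itertools

import networkx as nx
import numpy as np
import pytest

from infomod import (
    ModuleTree,
    connected_components,
    visit_rates,
    codelength,
    optimize_two_level,
    build_hierarchy,
    pagerank,
    label_modules,
)
from infomod.mapeq import write_tree_file, read_tree_file, tree_to_json, tree_from_json
from infomod.metrics import partition_nmi
from tests.conftest import make_clique


# -- independent oracles ------------------------------------------------------


def oracle_two_level_bits(g: nx.Graph, partition) -> float:
    """Two-level map equation straight from its entropy definition."""
    two_w = 2.0 * sum(d.get("weight", 1.0) for _, _, d in g.edges(data=True))
    p = {u: sum(d.get("weight", 1.0) for _, _, d in g.edges(u, data=True)) / two_w for u in g}

    def entropy(values):
        values = [v for v in values if v > 0]
        total = sum(values)
        return -sum((v / total) * math.log2(v / total) for v in values)

    exits = []
    for m in partition:
        exits.append(
            sum(
                d.get("weight", 1.0)
                for u, v, d in g.edges(data=True)
                if (u in m) != (v in m)
            )
            / two_w
        )
    q = sum(exits)
    bits = q * entropy(exits) if q > 0 else 0.0
    for m, qm in zip(partition, exits):
        inner = [qm] + [p[u] for u in m]
        bits += sum(inner) * entropy(inner)
    return bits


def set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def depth1_tree(g, partition):
    genes = frozenset(g.nodes)
    root = ModuleTree(path="", genes=genes)
    root.children = [
        ModuleTree(path=str(k), genes=frozenset(m)) for k, m in enumerate(partition, 1)
    ]
    return root


def random_connected_graph(n, rng):
    while True:
        g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(1 << 31)))
        if nx.is_connected(g) and g.number_of_edges() > n - 1:
            g = nx.relabel_nodes(g, {i: f"n{i}" for i in g})
            nx.set_edge_attributes(g, 1.0, "weight")
            return g


# -- connected components -----------------------------------------------------


class TestConnectedComponents:
    def test_edgeless_graph_gives_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("abcde")
        comps = connected_components(g)
        assert len(comps) == 5 and all(len(c) == 1 for c in comps)

    def test_single_clique(self):
        g = nx.Graph()
        make_clique(g, list("abcd"))
        assert len(connected_components(g)) == 1

    def test_ordering_size_then_min_id(self):
        g = nx.Graph()
        make_clique(g, ["z1", "z2", "z3"])
        make_clique(g, ["a1", "a2"])
        make_clique(g, ["b1", "b2"])
        comps = connected_components(g)
        assert [sorted(c)[0] for c in comps] == ["z1", "a1", "b1"]

    def test_amplicon_is_isolated_clique(self, small_net):
        net, truth = small_net
        amp = frozenset(truth.amplicon_genes)
        comps = connected_components(net)
        assert amp in comps
        sub = net.subgraph(amp)
        assert sub.number_of_edges() == len(amp) * (len(amp) - 1) // 2


# -- visit rates --------------------------------------------------------------


class TestVisitRates:
    def test_path_graph(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=1.0)
        g.add_edge("B", "C", weight=1.0)
        rates = visit_rates(g, {"A", "B", "C"})
        assert rates == pytest.approx({"A": 0.25, "B": 0.5, "C": 0.25})

    def test_regular_graph_uniform(self):
        g = nx.cycle_graph(6)
        rates = visit_rates(g, set(g.nodes))
        assert all(abs(v - 1 / 6) < 1e-12 for v in rates.values())

    def test_sums_to_one(self, small_net):
        net, _ = small_net
        for comp in connected_components(net):
            assert sum(visit_rates(net, comp).values()) == pytest.approx(1.0, abs=1e-12)

    def test_disconnected_input_rejected(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=1.0)
        g.add_edge("C", "D", weight=1.0)
        with pytest.raises(ValueError, match="connected"):
            visit_rates(g, {"A", "B", "C", "D"})


# -- codelength ---------------------------------------------------------------


class TestCodelength:
    def test_four_cycle_single_module_exactly_two_bits(self):
        g = nx.cycle_graph(4)
        tree = depth1_tree(g, [list(g.nodes)])
        assert codelength(g, tree) == pytest.approx(2.0, abs=1e-12)

    def test_barbell_matches_entropy_oracle(self, barbell6):
        partition = [["a1", "a2", "a3"], ["b1", "b2", "b3"]]
        tree = depth1_tree(barbell6, partition)
        mine = codelength(barbell6, tree)
        oracle = oracle_two_level_bits(barbell6, [set(m) for m in partition])
        assert mine == pytest.approx(oracle, abs=1e-12)
        one = codelength(barbell6, depth1_tree(barbell6, [list(barbell6.nodes)]))
        assert mine < one

    def test_barbell_two_triangle_partition_is_global_minimum(self, barbell6):
        nodes = sorted(barbell6.nodes)
        best, best_bits = None, np.inf
        for partition in set_partitions(nodes):
            bits = oracle_two_level_bits(barbell6, [set(m) for m in partition])
            if bits < best_bits:
                best, best_bits = partition, bits
        assert sorted(map(sorted, best)) == [["a1", "a2", "a3"], ["b1", "b2", "b3"]]
        tree = depth1_tree(barbell6, best)
        assert codelength(barbell6, tree) == pytest.approx(best_bits, abs=1e-12)

    def test_relabeling_invariance(self, barbell6):
        partition = [["a1", "a2", "a3"], ["b1", "b2", "b3"]]
        a = codelength(barbell6, depth1_tree(barbell6, partition))
        b = codelength(barbell6, depth1_tree(barbell6, partition[::-1]))
        assert a == pytest.approx(b, abs=1e-14)

    def test_invalid_partition_rejected(self, barbell6):
        tree = depth1_tree(barbell6, [["a1", "a2"], ["b1", "b2", "b3"]])  # a3 missing
        with pytest.raises(ValueError):
            codelength(barbell6, tree)

    def test_depth1_equals_two_level_formula_on_random_graphs(self, rng):
        for _ in range(5):
            g = random_connected_graph(8, rng)
            nodes = sorted(g.nodes)
            cut = len(nodes) // 2
            partition = [nodes[:cut], nodes[cut:]]
            tree = depth1_tree(g, partition)
            assert codelength(g, tree) == pytest.approx(
                oracle_two_level_bits(g, [set(m) for m in partition]), abs=1e-12
            )


# -- two-level optimizer ------------------------------------------------------


class TestOptimizeTwoLevel:
    def test_clique_stays_one_module(self):
        g = nx.Graph()
        make_clique(g, [f"c{i}" for i in range(7)])
        tree = optimize_two_level(g, frozenset(g.nodes), trials=5, seed=0)
        assert len(tree.children) == 1

    def test_two_cliques_exact_recovery(self, two_cliques8):
        g, truth = two_cliques8
        tree = optimize_two_level(g, frozenset(g.nodes), trials=10, seed=1)
        found = {g_: m.path for m in tree.children for g_ in m.genes}
        want = {g_: i for i, c in enumerate(truth) for g_ in c}
        assert partition_nmi(found, want) == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_on_random_7_node_graphs(self, rng):
        hits = 0
        for _ in range(20):
            g = random_connected_graph(7, rng)
            nodes = sorted(g.nodes)
            brute = min(
                oracle_two_level_bits(g, [set(m) for m in p])
                for p in set_partitions(nodes)
            )
            tree = optimize_two_level(g, frozenset(nodes), trials=10, seed=7)
            assert tree.codelength >= brute - 1e-9  # never beats the true minimum
            if tree.codelength <= brute + 1e-9:
                hits += 1
        assert hits >= 19

    def test_never_above_one_module_baseline(self, rng):
        for _ in range(5):
            g = random_connected_graph(9, rng)
            tree = optimize_two_level(g, frozenset(g.nodes), trials=3, seed=2)
            baseline = codelength(g, depth1_tree(g, [list(g.nodes)]))
            assert tree.codelength <= baseline + 1e-12

    def test_deterministic(self, two_cliques8):
        g, _ = two_cliques8
        a = optimize_two_level(g, frozenset(g.nodes), trials=5, seed=3)
        b = optimize_two_level(g, frozenset(g.nodes), trials=5, seed=3)
        assert tree_to_json(a) == tree_to_json(b)

    def test_empty_component_rejected(self, two_cliques8):
        g, _ = two_cliques8
        with pytest.raises(ValueError, match="empty"):
            optimize_two_level(g, frozenset(), trials=1, seed=0)


# -- hierarchy ----------------------------------------------------------------


class TestBuildHierarchy:
    def test_clique_is_depth_one(self):
        g = nx.Graph()
        make_clique(g, [f"c{i}" for i in range(6)])
        tree = build_hierarchy(g, frozenset(g.nodes), trials=5, seed=0)
        assert tree.max_depth() == 1

    def test_nested_benchmark_recovers_both_levels(self, nested_benchmark):
        g, cliques = nested_benchmark
        tree = build_hierarchy(g, frozenset(g.nodes), trials=10, seed=1)
        assert len(tree.children) == 2
        top = {frozenset(m.genes) for m in tree.children}
        assert top == {
            frozenset(cliques["A1"] | cliques["A2"]),
            frozenset(cliques["B1"] | cliques["B2"]),
        }
        leaves = {frozenset(m.genes) for m in tree.walk() if m.is_leaf}
        assert leaves == {frozenset(c) for c in cliques.values()}

    def test_hierarchical_not_above_flat(self, nested_benchmark):
        g, _ = nested_benchmark
        tree = build_hierarchy(g, frozenset(g.nodes), trials=10, seed=1)
        flat = optimize_two_level(g, frozenset(g.nodes), trials=10, seed=1)
        assert tree.codelength <= flat.codelength + 1e-10

    def test_partition_valid_at_every_level(self, small_net):
        net, _ = small_net
        for comp in connected_components(net):
            if len(comp) < 3:
                continue
            tree = build_hierarchy(net, comp, trials=5, seed=4)
            tree.validate()
            assert tree.genes == frozenset(comp)

    def test_deterministic_across_runs(self, nested_benchmark):
        g, _ = nested_benchmark
        a = build_hierarchy(g, frozenset(g.nodes), trials=5, seed=9)
        b = build_hierarchy(g, frozenset(g.nodes), trials=5, seed=9)
        assert tree_to_json(a) == tree_to_json(b)

    def test_min_split_respected(self, nested_benchmark):
        g, _ = nested_benchmark
        tree = build_hierarchy(g, frozenset(g.nodes), trials=5, seed=1, min_split=100)
        assert tree.max_depth() <= 2  # supermodule level allowed, no subdivision below top

    def test_bad_arguments_rejected(self, nested_benchmark):
        g, _ = nested_benchmark
        with pytest.raises(ValueError):
            build_hierarchy(g, frozenset(g.nodes), max_depth=0)
        with pytest.raises(ValueError):
            build_hierarchy(g, frozenset(g.nodes), min_split=1)


# -- PageRank and labeling ----------------------------------------------------


def pagerank_linear_solve(g: nx.Graph, damping=0.85):
    nodes = sorted(g.nodes)
    n = len(nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    W = np.zeros((n, n))
    for u, v, d in g.edges(data=True):
        w = d.get("weight", 1.0)
        W[idx[u], idx[v]] += w
        if u != v:
            W[idx[v], idx[u]] += w
    T = W / W.sum(axis=1, keepdims=True)
    x = np.linalg.solve(np.eye(n) - damping * T.T, np.full(n, (1 - damping) / n))
    return {u: x[idx[u]] for u in nodes}


class TestPageRank:
    def test_star_matches_linear_solve(self):
        g = nx.star_graph(4)
        scores = pagerank(g, set(g.nodes))
        oracle = pagerank_linear_solve(g)
        for u in g:
            assert scores[u] == pytest.approx(oracle[u], abs=1e-8)

    def test_path_matches_linear_solve(self):
        g = nx.path_graph(6)
        scores = pagerank(g, set(g.nodes))
        oracle = pagerank_linear_solve(g)
        for u in g:
            assert scores[u] == pytest.approx(oracle[u], abs=1e-8)

    def test_random_graphs_match_linear_solve(self, rng):
        for _ in range(20):
            g = random_connected_graph(8, rng)
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.1, 2.0))
            scores = pagerank(g, set(g.nodes))
            oracle = pagerank_linear_solve(g)
            for u in g:
                assert scores[u] == pytest.approx(oracle[u], abs=1e-8)

    def test_scores_sum_to_one(self, small_net):
        net, _ = small_net
        comp = connected_components(net)[0]
        assert sum(pagerank(net, comp).values()) == pytest.approx(1.0, abs=1e-9)

    def test_regular_graph_uniform_any_damping(self):
        g = nx.cycle_graph(8)
        for damping in (0.3, 0.85, 0.99):
            scores = pagerank(g, set(g.nodes), damping=damping)
            assert all(abs(v - 1 / 8) < 1e-9 for v in scores.values())

    def test_bad_damping_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError):
            pagerank(g, set(g.nodes), damping=1.0)


class TestLabelModules:
    def test_singleton_module(self):
        tree = ModuleTree(path="", genes=frozenset({"X"}))
        label_modules(tree, {"X": 1.0})
        assert tree.label == "X"

    def test_star_hub_is_label(self):
        g = nx.star_graph(5)
        g = nx.relabel_nodes(g, {0: "hub", **{i: f"leaf{i}" for i in range(1, 6)}})
        scores = pagerank(g, set(g.nodes))
        tree = ModuleTree(path="", genes=frozenset(g.nodes))
        label_modules(tree, scores)
        assert tree.label == "hub"
        assert scores["hub"] == max(scores.values())

    def test_tie_breaks_lexicographically(self):
        tree = ModuleTree(path="", genes=frozenset({"B", "A"}))
        label_modules(tree, {"A": 0.5, "B": 0.5})
        assert tree.label == "A"

    def test_missing_score_rejected(self):
        tree = ModuleTree(path="", genes=frozenset({"A", "B"}))
        with pytest.raises(ValueError, match="score"):
            label_modules(tree, {"A": 1.0})


# -- interchange --------------------------------------------------------------


class TestInterchange:
    def test_tree_file_round_trip(self, nested_benchmark, tmp_path):
        g, _ = nested_benchmark
        comp = frozenset(g.nodes)
        tree = build_hierarchy(g, comp, trials=5, seed=1)
        rates = visit_rates(g, comp)
        path = tmp_path / "out.tree"
        write_tree_file(tree, rates, path)
        assignment = read_tree_file(path)
        assert assignment == tree.leaf_assignment()

    def test_json_round_trip(self, nested_benchmark, tmp_path):
        g, _ = nested_benchmark
        tree = build_hierarchy(g, frozenset(g.nodes), trials=5, seed=1)
        label_modules(tree, pagerank(g, frozenset(g.nodes)))
        path = tmp_path / "tree.json"
        tree_to_json(tree, path)
        back = tree_from_json(path)
        assert tree_to_json(back) == tree_to_json(tree)
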