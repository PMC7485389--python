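import math

import networkx as nx
import pytest

from comorbnet.mapeq import (
    detect_modules,
    label_modules,
    map_equation,
    pagerank,
    pagerank_dense,
)

from conftest import iter_set_partitions, small_connected_graphs


def entropy_bits(ps):
    return -sum(p * math.log2(p) for p in ps if p > 0)


class TestPagerank:
    def test_two_node_path_is_symmetric(self):
        pr = pagerank(nx.path_graph(2))
        assert pr[0] == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize("g", [nx.cycle_graph(6), nx.complete_graph(5),
                                   nx.random_regular_graph(4, 10, seed=3)])
    def test_uniform_on_regular_graphs(self, g):
        pr = pagerank(g)
        for v in g:
            assert pr[v] == pytest.approx(1 / g.number_of_nodes(), abs=1e-9)

    def test_star_matches_dense_solve(self):
        g = nx.star_graph(3)
        pr = pagerank(g, tol=1e-12)
        ref = pagerank_dense(g)
        for v in g:
            assert pr[v] == pytest.approx(ref[v], abs=1e-11)

    def test_sums_to_one(self):
        pr = pagerank(nx.barbell_graph(4, 2))
        assert sum(pr.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_graph_fatal(self):
        with pytest.raises(ValueError):
            pagerank(nx.Graph())


class TestMapEquation:
    def test_one_module_equals_flow_entropy(self):
        g = nx.barbell_graph(3, 1)
        flow = pagerank(g)
        score = map_equation(g, {v: 0 for v in g}, flow)
        assert score.index_term == 0.0
        assert score.codelength == pytest.approx(entropy_bits(flow.values()), abs=1e-9)

    def test_two_disconnected_triangles_hand_derivation(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        flow = {v: 1 / 6 for v in g}
        two = map_equation(g, {v: 0 if v < 3 else 1 for v in g}, flow, damping=1.0)
        one = map_equation(g, {v: 0 for v in g}, flow, damping=1.0)
        assert two.codelength == pytest.approx(math.log2(3), abs=1e-12)
        assert one.codelength == pytest.approx(math.log2(6), abs=1e-12)

    def test_additivity_invariant(self):
        g = nx.connected_watts_strogatz_graph(12, 4, 0.2, seed=1)
        flow = pagerank(g)
        part = {v: v % 3 for v in g}
        s = map_equation(g, part, flow)
        assert s.codelength == pytest.approx(s.index_term + sum(s.module_terms.values()),
                                             abs=1e-9)
        assert s.codelength >= 0

    def test_partition_mismatch_fatal(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError):
            map_equation(g, {0: 0, 1: 0}, pagerank(g))

    def test_splitting_disconnected_components_never_worse(self):
        # merging two disconnected cliques into one module never decreases L
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(3))
        flow = pagerank(g)
        split = {v: 0 if v < 4 else 1 for v in g}
        merged = {v: 0 for v in g}
        assert (
            map_equation(g, split, flow).codelength
            <= map_equation(g, merged, flow).codelength + 1e-12
        )


class TestDetectModules:
    def test_single_clique_is_one_module(self):
        part = detect_modules(nx.complete_graph(4), seed=0)
        assert len(part.modules) == 1

    def test_two_cliques_bridge_split_exactly(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g.add_edge(0, 4)
        part = detect_modules(g, seed=0)
        groups = {}
        for v, m in part.assignment.items():
            groups.setdefault(m, set()).add(v)
        assert sorted(map(sorted, groups.values())) == [[0, 1, 2, 3], [4, 5, 6, 7]]

    def test_never_worse_than_one_module(self):
        for name, g in small_connected_graphs().items():
            flow = pagerank(g)
            part = detect_modules(g, seed=3, flow=flow)
            one = map_equation(g, {v: 0 for v in g}, flow).codelength
            assert part.codelength <= one + 1e-9, name

    def test_matches_exhaustive_optimum_on_bridge_graph(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g.add_edge(0, 4)
        flow = pagerank(g)
        best = min(
            map_equation(
                g, {v: i for i, block in enumerate(p) for v in block}, flow
            ).codelength
            for p in iter_set_partitions(g.nodes)
        )
        part = detect_modules(g, seed=0, flow=flow)
        assert part.codelength == pytest.approx(best, abs=1e-9)

    def test_permutation_invariance(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g.add_edge(0, 4)
        relabel = {v: 7 - v for v in g}
        h = nx.relabel_nodes(g, relabel)
        pg = detect_modules(g, seed=5)
        ph = detect_modules(h, seed=5)
        groups_g = {frozenset(relabel[v] for v in info.members) for info in pg.modules.values()}
        groups_h = {frozenset(info.members) for info in ph.modules.values()}
        assert groups_g == groups_h

    def test_deterministic_given_seed(self):
        g = nx.connected_watts_strogatz_graph(20, 4, 0.3, seed=11)
        a = detect_modules(g, seed=42).assignment
        b = detect_modules(g, seed=42).assignment
        assert a == b

    def test_single_node_graph(self):
        part = detect_modules(nx.empty_graph(1), seed=0)
        assert len(part.modules) == 1 and part.codelength == pytest.approx(0.0, abs=1e-12)


class TestLabels:
    def test_max_visit_rate_wins(self):
        g = nx.star_graph(3)
        flow = pagerank(g)
        part = detect_modules(g, seed=0, flow=flow)
        label_modules(part, flow)
        assert all(label == "0" for label in part.labels.values())  # hub of the star

    def test_tie_breaks_lexicographic(self):
        g = nx.Graph([("B00", "A00")])
        flow = {"A00": 0.5, "B00": 0.5}
        part = detect_modules(g, seed=0, flow=flow)
        label_modules(part, flow)
        assert set(part.labels.values()) == {"A00"}

    def test_name_table_join(self):
        g = nx.Graph([("I10.X", "N18.9")])
        flow = {"I10.X": 0.6, "N18.9": 0.4}
        part = detect_modules(g, seed=0, flow=flow)
        label_modules(part, flow, {"I10.X": "essential hypertension"})
        assert "essential hypertension" in list(part.labels.values())[0]
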