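import itertools
import math

import networkx as nx
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def records_tsv(tmp_path):
    """Write a long-format discharge table and return its path."""

    def _write(rows, name="records.tsv"):
        path = tmp_path / name
        lines = ["record_id\tage\tsex\ticd10"]
        lines += ["\t".join(str(x) for x in row) for row in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


def hypergeom_enumeration(N: int, n_a: int, n_b: int, k: int) -> float:
    """Brute-force upper-tail probability: enumerate every size-n_b draw
    from the N records and count draws overlapping the fixed n_a set in
    at least k elements. Independent oracle for small N."""
    marked = set(range(n_a))
    hits = total = 0
    for draw in itertools.combinations(range(N), n_b):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


def iter_set_partitions(items):
    """All set partitions via restricted-growth strings (exhaustive oracle)."""
    items = list(items)
    n = len(items)
    if n == 0:
        yield []
        return
    rgs = [0] * n

    def rec(i, max_used):
        if i == n:
            blocks = {}
            for item, g in zip(items, rgs):
                blocks.setdefault(g, []).append(item)
            yield list(blocks.values())
            return
        for g in range(max_used + 2):
            rgs[i] = g
            yield from rec(i + 1, max(max_used, g))

    yield from rec(1, 0)


def small_connected_graphs():
    """A spread of connected test graphs with n <= 8 nodes."""
    two_cliques = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
    two_cliques.add_edge(0, 4)
    two_tri = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
    two_tri.add_edge(0, 3)
    return {
        "path6": nx.path_graph(6),
        "cycle8": nx.cycle_graph(8),
        "star8": nx.star_graph(7),
        "clique5": nx.complete_graph(5),
        "two_cliques_bridge": two_cliques,
        "two_triangles_bridge": two_tri,
        "barbell": nx.barbell_graph(3, 1),
        "gnp8": nx.connected_watts_strogatz_graph(8, 4, 0.3, seed=7),
    }
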