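"""Comorbidity network construction and topology.

Two diseases are linked when they occur in the same discharge record more
often than expected by chance: a one-sided (upper-tail) hypergeometric test
on the 2x2 co-occurrence margins, with Benjamini-Hochberg FDR correction
across all pairs that co-occur at least once, and edges retained at
q < alpha (strict). Each network — the full cohort and every age bracket —
forms its own FDR family.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .records_io import RecordSet

PAIR_COLUMNS = ["code_a", "code_b", "n_a", "n_b", "k", "p", "q"]


@dataclass
class PairCounts:
    """Raw co-occurrence evidence: N, per-code prevalence, and pair counts."""

    n_records: int
    prevalence: dict[str, int]
    pairs: dict[tuple[str, str], int]  # (code_a < code_b) -> k


def count_pairs(rs: RecordSet) -> PairCounts:
    """Count per-code prevalence and unordered pair co-occurrence.

    Only pairs observed together in at least one record are enumerated;
    never-co-occurring pairs are not part of the test family.
    """
    if rs.n_records == 0:
        raise ValueError("empty RecordSet")
    prevalence: Counter = Counter()
    pairs: Counter = Counter()
    for rec in rs:
        codes = sorted(rec.codes)
        prevalence.update(codes)
        for a, b in itertools.combinations(codes, 2):
            pairs[(a, b)] += 1
    return PairCounts(rs.n_records, dict(prevalence), dict(pairs))


def hypergeom_upper_tail(N: int, n_a: int, n_b: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, n_a, n_b).

    The probability that two diseases carried by n_a and n_b of N records
    share at least k records under random assortment. Symmetric in
    (n_a, n_b); k = 0 gives 1 exactly.
    """
    if not (0 <= n_a <= N and 0 <= n_b <= N):
        raise ValueError(f"inconsistent counts: n_a={n_a}, n_b={n_b}, N={N}")
    if not (0 <= k <= min(n_a, n_b)):
        raise ValueError(f"inconsistent counts: k={k}, n_a={n_a}, n_b={n_b}")
    if k == 0:
        return 1.0
    # survival function is P(X > k-1) = P(X >= k)
    return float(hypergeom.sf(k - 1, N, n_a, n_b))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pair_table(counts: PairCounts) -> pd.DataFrame:
    """Per-pair statistics table with columns code_a..q (one FDR family)."""
    rows = []
    for (a, b), k in sorted(counts.pairs.items()):
        n_a, n_b = counts.prevalence[a], counts.prevalence[b]
        rows.append((a, b, n_a, n_b, k, hypergeom_upper_tail(counts.n_records, n_a, n_b, k)))
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS[:6])
    df["q"] = bh_fdr(df["p"].to_numpy()) if len(df) else []
    return df


@dataclass
class ComorbidityNetwork:
    """Undirected simple graph of ICD-10 codes linked by significant co-occurrence.

    ``graph`` nodes carry a ``prevalence`` attribute (records with the code);
    edges carry k, p, q. ``pairs`` is the full tested pair table (the FDR
    family), including non-significant pairs.
    """

    graph: nx.Graph
    alpha: float
    n_records: int
    pairs: pd.DataFrame

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    counts: PairCounts,
    alpha: float = 0.05,
    min_k: int = 1,
    include_isolates: bool = False,
) -> ComorbidityNetwork:
    """Keep edges with q < alpha (strict) and k >= min_k.

    Nodes default to edge-incident codes only; ``include_isolates`` adds
    every prevalent code even when none of its pairings is significant.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    df = pair_table(counts)
    g = nx.Graph()
    if include_isolates:
        g.add_nodes_from(counts.prevalence)
    sig = df[(df["q"] < alpha) & (df["k"] >= min_k)]
    for row in sig.itertuples(index=False):
        g.add_edge(row.code_a, row.code_b, k=int(row.k), p=float(row.p), q=float(row.q))
    nx.set_node_attributes(
        g, {c: counts.prevalence.get(c, 0) for c in g.nodes}, "prevalence"
    )
    return ComorbidityNetwork(g, alpha, counts.n_records, df)


def network_from_records(rs: RecordSet, alpha: float = 0.05, min_k: int = 1,
                         include_isolates: bool = False) -> ComorbidityNetwork:
    return build_network(count_pairs(rs), alpha=alpha, min_k=min_k,
                         include_isolates=include_isolates)


# --- topology -----------------------------------------------------------

def density_from_counts(n_nodes: int, n_edges: int) -> float:
    if n_nodes < 2:
        return math.nan
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def average_degree_from_counts(n_nodes: int, n_edges: int) -> float:
    if n_nodes < 1:
        return math.nan
    return 2.0 * n_edges / n_nodes


def degree_centralization_from_counts(n_nodes: int, n_edges: int, k_max: int) -> float:
    """Freeman degree centralization from aggregate counts.

    sum_i (k_max - k_i) = n*k_max - 2E, normalized by the star-graph
    maximum (n-1)(n-2); 1 for a star, 0 for any regular graph.
    """
    if n_nodes < 3:
        return math.nan
    return (n_nodes * k_max - 2.0 * n_edges) / ((n_nodes - 1) * (n_nodes - 2))


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    density: float
    average_degree: float
    centralization: float
    avg_clustering: float

    def as_dict(self) -> dict:
        return {
            "nodes": self.n_nodes,
            "links": self.n_edges,
            "density": self.density,
            "average_degree": self.average_degree,
            "centralization": self.centralization,
            "avg_clustering": self.avg_clustering,
        }


def topology(net: ComorbidityNetwork | nx.Graph) -> TopologySummary:
    """Whole-graph topology row: density, mean degree, Freeman centralization,
    mean local clustering (degree-<2 nodes contribute 0).

    Degenerate sizes yield NaN fields rather than exceptions.
    """
    g = net.graph if isinstance(net, ComorbidityNetwork) else net
    n, e = g.number_of_nodes(), g.number_of_edges()
    degrees = [d for _, d in g.degree()]
    k_max = max(degrees) if degrees else 0
    return TopologySummary(
        n_nodes=n,
        n_edges=e,
        density=density_from_counts(n, e),
        average_degree=average_degree_from_counts(n, e),
        centralization=degree_centralization_from_counts(n, e, k_max),
        avg_clustering=nx.average_clustering(g) if n >= 1 else math.nan,
    )


def top_k_by_degree(net: ComorbidityNetwork | nx.Graph, k: int) -> list[tuple[str, int]]:
    """Top-k hubs: descending degree, ties broken lexicographically by code."""
    if k < 1:
        raise ValueError("k must be >= 1")
    g = net.graph if isinstance(net, ComorbidityNetwork) else net
    ranked = sorted(g.degree(), key=lambda cd: (-cd[1], cd[0]))
    return ranked[:k]


# --- export -------------------------------------------------------------

def write_edge_table(net: ComorbidityNetwork, path) -> None:
    """Significant edges as TSV (code_a, code_b, n_a, n_b, k, p, q)."""
    sig = net.pairs[(net.pairs["q"] < net.alpha) & (net.pairs["k"] >= 1)]
    sig = sig[sig.apply(lambda r: net.graph.has_edge(r["code_a"], r["code_b"]), axis=1)]
    sig.to_csv(path, sep="\t", index=False)


def write_graphml(net: ComorbidityNetwork, path, partition: dict[str, int] | None = None) -> None:
    g = net.graph.copy()
    nx.set_node_attributes(g, dict(g.degree()), "degree")
    if partition is not None:
        nx.set_node_attributes(g, partition, "module")
    nx.write_graphml(g, path)
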