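"""Flow-based module detection on the comorbidity network.

The two-level map equation scores a partition M of the network by the
description length (in bits) of a random walk encoded with one index
codebook for between-module moves and one codebook per module:

    L(M) = q * H(Q) + sum_m p_m * H(P_m)

where q is the total module-exit flow, H(Q) the entropy of per-module exit
flows, and each module codebook covers its members' visit rates plus the
module's exit event. Node visit rates come from PageRank on the undirected
graph (damped walk, uniform teleportation); teleportation is *unrecorded*:
it contributes to visit rates but not to exit flows, so only edge-crossing
walk flow counts as leaving a module.

Minimizing L(M) is done by a greedy single-node-move search from the
all-singletons start, repeated over shuffled node orders (restarts), which
is the agglomerative core of the Infomap heuristic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .conet import ComorbidityNetwork


def _as_graph(net) -> nx.Graph:
    return net.graph if isinstance(net, ComorbidityNetwork) else net


def _plogp(x: float) -> float:
    return x * math.log2(x) if x > 0.0 else 0.0


# --- PageRank flow ------------------------------------------------------

def pagerank(net, damping: float = 0.85, tol: float = 1e-12) -> dict:
    """Stationary visit rates of the damped random walk with teleportation.

    Convergence criterion: L1 change between successive iterates < tol.
    Deterministic for a given graph. Rates sum to 1.
    """
    g = _as_graph(net)
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("pagerank on empty graph")
    if n == 1:
        return {next(iter(g.nodes)): 1.0}
    # networkx converges when the L1 error drops below n * tol
    return nx.pagerank(g, alpha=damping, tol=tol / n, max_iter=1000)


def pagerank_dense(net, damping: float = 0.85) -> dict:
    """Dense linear-system PageRank, (I - d P^T) x = (1-d)/n, as an
    independent cross-check of the power iteration (small graphs only)."""
    g = _as_graph(net)
    nodes = list(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    P = np.zeros((n, n))
    for v in nodes:
        nbrs = list(g.neighbors(v))
        if nbrs:
            for w in nbrs:
                P[idx[v], idx[w]] = 1.0 / len(nbrs)
        else:  # dangling: uniform jump
            P[idx[v], :] = 1.0 / n
    x = np.linalg.solve(np.eye(n) - damping * P.T, np.full(n, (1.0 - damping) / n))
    x /= x.sum()
    return {v: float(x[idx[v]]) for v in nodes}


# --- map equation -------------------------------------------------------

@dataclass
class MapEquationScore:
    codelength: float
    index_term: float
    module_terms: dict[int, float]

    def __post_init__(self) -> None:
        total = self.index_term + sum(self.module_terms.values())
        assert abs(total - self.codelength) < 1e-9


def _module_exit_flows(g: nx.Graph, assignment: dict, flow: dict, damping: float) -> dict[int, float]:
    """Per-module exit flow: damped walk flow along edges leaving the module."""
    q: dict[int, float] = {}
    for v in g.nodes:
        deg = g.degree(v)
        if deg == 0:
            continue
        mv = assignment[v]
        out = sum(1 for w in g.neighbors(v) if assignment[w] != mv)
        if out:
            q[mv] = q.get(mv, 0.0) + damping * flow[v] * out / deg
    return q


def map_equation(net, assignment: dict, flow: dict, damping: float = 0.85) -> MapEquationScore:
    """Two-level map-equation codelength of a partition, in bits.

    ``assignment`` maps every node to a module id; ``flow`` is the PageRank
    visit-rate distribution of the same graph. A one-module partition gives
    the plain Shannon entropy of the visit rates.
    """
    g = _as_graph(net)
    if set(assignment) != set(g.nodes):
        raise ValueError("partition does not cover exactly the graph's nodes")
    modules = sorted(set(assignment.values()))
    qm = _module_exit_flows(g, assignment, flow, damping)
    q_total = sum(qm.values())
    index_term = _plogp(q_total) - sum(_plogp(x) for x in qm.values())
    module_terms: dict[int, float] = {}
    for m in modules:
        members = [v for v in g.nodes if assignment[v] == m]
        pm = qm.get(m, 0.0) + sum(flow[v] for v in members)
        term = _plogp(pm) - _plogp(qm.get(m, 0.0)) - sum(_plogp(flow[v]) for v in members)
        module_terms[m] = term
    return MapEquationScore(index_term + sum(module_terms.values()), index_term, module_terms)


# --- greedy search ------------------------------------------------------

class _GreedyState:
    """Incremental map-equation bookkeeping for single-node moves.

    L = plogp(Q) - 2*sum_m plogp(q_m) + sum_m plogp(q_m + F_m) - sum_i plogp(p_i)

    with Q total exit flow, q_m module exit flows, F_m module flow sums;
    the last term is partition-independent. Moves update only the source
    and destination modules.
    """

    def __init__(self, g: nx.Graph, flow: dict, damping: float):
        self.g = g
        self.d = damping
        self.flow = flow
        self.deg = dict(g.degree())
        self.assign = {v: i for i, v in enumerate(g.nodes)}
        self.members: dict[int, set] = {m: {v} for v, m in self.assign.items()}
        self.F = {m: flow[v] for v, m in self.assign.items()}
        self.q: dict[int, float] = {}
        for v in g.nodes:
            if self.deg[v]:
                out = sum(1 for w in g.neighbors(v) if self.assign[w] != self.assign[v])
                self.q[self.assign[v]] = self.d * flow[v] * out / self.deg[v]
            else:
                self.q[self.assign[v]] = 0.0
        self.Q = sum(self.q.values())
        self.const = -sum(_plogp(p) for p in flow.values())
        self._next_id = len(self.assign)

    def codelength(self) -> float:
        return (
            _plogp(self.Q)
            - 2.0 * sum(_plogp(x) for x in self.q.values())
            + sum(_plogp(self.q[m] + self.F[m]) for m in self.members)
            + self.const
        )

    def _move_deltas(self, v, target: int):
        """New (q_A, q_B) if v moved from its module A to module B."""
        A = self.assign[v]
        dv = self.deg[v]
        fv = self.flow[v]
        in_A = in_B = 0
        wsum_A = wsum_B = 0.0
        for w in self.g.neighbors(v):
            mw = self.assign[w]
            if mw == A:
                in_A += 1
                wsum_A += self.flow[w] / self.deg[w]
            elif mw == target:
                in_B += 1
                wsum_B += self.flow[w] / self.deg[w]
        out_share = self.d * fv / dv if dv else 0.0
        qA_new = self.q[A] - out_share * (dv - in_A) + self.d * wsum_A
        qB_old = self.q.get(target, 0.0)
        qB_new = qB_old + out_share * (dv - in_B) - self.d * wsum_B
        return qA_new, qB_old, qB_new

    def try_move(self, v, target: int) -> float:
        """Codelength change if v moves to module ``target`` (may be new)."""
        A = self.assign[v]
        if target == A:
            return 0.0
        qA, qB_old, qB = self._move_deltas(v, target)
        FA_new = self.F[A] - self.flow[v]
        FB_new = self.F.get(target, 0.0) + self.flow[v]
        Q_new = self.Q + (qA - self.q[A]) + (qB - qB_old)
        delta = _plogp(Q_new) - _plogp(self.Q)
        delta -= 2.0 * (_plogp(qA) + _plogp(qB) - _plogp(self.q[A]) - _plogp(qB_old))
        delta += _plogp(qA + FA_new) + _plogp(qB + FB_new)
        delta -= _plogp(self.q[A] + self.F[A]) + _plogp(qB_old + self.F.get(target, 0.0))
        return delta

    def apply_move(self, v, target: int) -> None:
        A = self.assign[v]
        qA, qB_old, qB = self._move_deltas(v, target)
        self.Q += (qA - self.q[A]) + (qB - qB_old)
        self.q[A] = qA
        self.q[target] = qB
        self.F[A] -= self.flow[v]
        self.F[target] = self.F.get(target, 0.0) + self.flow[v]
        self.members[A].discard(v)
        self.members.setdefault(target, set()).add(v)
        self.assign[v] = target
        if not self.members[A]:
            del self.members[A], self.F[A], self.q[A]

    def new_module_id(self) -> int:
        self._next_id += 1
        return self._next_id


@dataclass
class ModuleInfo:
    module_id: int
    members: frozenset
    flow: float
    exit_flow: float
    label: str | None = None


@dataclass
class ModulePartition:
    assignment: dict
    modules: dict[int, ModuleInfo]
    codelength: float
    damping: float = 0.85
    labels: dict[int, str] = field(default_factory=dict)


def _canonical(assignment: dict) -> dict:
    """Renumber modules 1..M in order of their lexicographically smallest member."""
    reps = {}
    for v, m in assignment.items():
        if m not in reps or str(v) < str(reps[m]):
            reps[m] = v
    order = {m: i + 1 for i, (m, _) in enumerate(sorted(reps.items(), key=lambda kv: str(kv[1])))}
    return {v: order[m] for v, m in assignment.items()}


def detect_modules(
    net,
    seed: int = 0,
    n_restarts: int = 10,
    damping: float = 0.85,
    flow: dict | None = None,
) -> ModulePartition:
    """Greedy map-equation minimization with seeded random restarts.

    Every node starts in its own module; sweeps over a shuffled node order
    move each node to the neighboring module (or a fresh singleton) that
    most decreases the codelength, until a full sweep makes no move. The
    best of ``n_restarts`` runs is returned; the result never scores worse
    than the one-module partition. Deterministic given (seed, n_restarts).
    """
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if flow is None:
        flow = pagerank(g, damping=damping)
    nodes = list(g.nodes)
    rng = np.random.default_rng(seed)
    best_assign: dict | None = None
    best_L = math.inf
    for _ in range(max(1, n_restarts)):
        state = _GreedyState(g, flow, damping)
        order = list(nodes)
        improved = True
        while improved:
            improved = False
            rng.shuffle(order)
            for v in order:
                candidates = {state.assign[w] for w in g.neighbors(v)}
                candidates.discard(state.assign[v])
                if len(state.members[state.assign[v]]) > 1:
                    candidates.add(state.new_module_id())
                best_delta, best_t = -1e-12, None
                for t in sorted(candidates):
                    delta = state.try_move(v, t)
                    if delta < best_delta:
                        best_delta, best_t = delta, t
                if best_t is not None:
                    state.apply_move(v, best_t)
                    improved = True
        L = state.codelength()
        if L < best_L - 1e-12:
            best_L, best_assign = L, dict(state.assign)
    # never worse than the trivial one-module partition
    one = {v: 0 for v in nodes}
    L_one = map_equation(g, one, flow, damping).codelength
    if best_assign is None or L_one < best_L - 1e-12:
        best_assign, best_L = one, L_one
    assignment = _canonical(best_assign)
    score = map_equation(g, assignment, flow, damping)
    qm = _module_exit_flows(g, assignment, flow, damping)
    modules = {}
    for m in sorted(set(assignment.values())):
        members = frozenset(v for v, mm in assignment.items() if mm == m)
        modules[m] = ModuleInfo(m, members, sum(flow[v] for v in members), qm.get(m, 0.0))
    return ModulePartition(assignment, modules, score.codelength, damping)


def label_modules(partition: ModulePartition, flow: dict,
                  name_table: dict[str, str] | None = None) -> ModulePartition:
    """Label each module by its member with the highest PageRank visit rate
    (ties broken by lexicographically smallest code); optionally append a
    human-readable disease name."""
    for m, info in partition.modules.items():
        code = min(info.members, key=lambda c: (-flow[c], str(c)))
        label = str(code)
        if name_table and code in name_table:
            label = f"{code} ({name_table[code]})"
        info.label = label
        partition.labels[m] = label
    return partition
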