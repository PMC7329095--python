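"""Orienting a CI-map into a BIC-scored Bayesian network.

Pipeline: sepset-driven v-structure detection produces a PDAG, the standard
orientation (Meek) rules are closed to a fixpoint, and the remaining
undirected edges are oriented by sweeping the nodes in a mutual-information
order (weakest-first, strongest-first, or a seeded random permutation),
reversing any orientation that would close a directed cycle.  Candidate DAGs
are compared by the BIC score

    BIC = sum_i ln P_hat(x_i | parents(x_i)) - ln(N)/2 * Dim_G

with maximum-likelihood count estimates and Dim_G the number of independent
CPT parameters.  ``cimap_to_dag`` uses the strongest-first DAG as a baseline
and keeps the best of ``max_iter`` random-order restarts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .bn import DiscreteDataset
from .skeleton import CIMap

__all__ = [
    "PDAG",
    "OrderPolicy",
    "ScoredDag",
    "orient_v_structures",
    "rule_closure",
    "extend_to_dag",
    "bic_score",
    "cimap_to_dag",
]


@dataclass(frozen=True)
class OrderPolicy:
    kind: str = "TSF"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("TWF", "TSF", "random"):
            raise ValueError("order policy must be TWF, TSF or random")
        if (self.kind == "random") != (self.seed is not None):
            raise ValueError("seed must be given iff kind is random")


@dataclass
class PDAG:
    """Partially directed graph: disjoint directed and undirected edge sets
    with an acyclic directed part."""

    nodes: tuple[str, ...]
    directed: set[tuple[str, str]]
    undirected: set[frozenset]

    def __post_init__(self) -> None:
        for a, b in self.directed:
            if frozenset((a, b)) in self.undirected:
                raise ValueError(f"edge {a}-{b} is both directed and undirected")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("directed part contains a cycle")

    def copy(self) -> "PDAG":
        return PDAG(self.nodes, set(self.directed), set(self.undirected))

    def adjacent(self, a: str, b: str) -> bool:
        return (
            (a, b) in self.directed
            or (b, a) in self.directed
            or frozenset((a, b)) in self.undirected
        )

    def skeleton(self) -> set[frozenset]:
        return {frozenset(e) for e in self.directed} | set(self.undirected)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PDAG)
            and set(self.nodes) == set(other.nodes)
            and self.directed == other.directed
            and self.undirected == other.undirected
        )


@dataclass
class ScoredDag:
    """A fully directed extension with its BIC score and provenance."""

    dag: nx.DiGraph
    bic: float
    order_used: tuple[str, ...]
    policy: str

    def to_dot(self) -> str:
        lines = ["digraph G {"]
        for n in sorted(self.dag.nodes):
            lines.append(f'  "{n}";')
        for a, b in sorted(self.dag.edges):
            lines.append(f'  "{a}" -> "{b}";')
        lines.append("}")
        return "\n".join(lines)


def orient_v_structures(cimap: CIMap) -> PDAG:
    """Orient every unshielded triple X-Z-Y with Z outside sepset(X, Y) as
    the collider X->Z<-Y; conflicts are resolved first-processed-wins with
    triples visited in sorted (X, Z, Y) order."""
    adj = cimap.adjacency()
    directed: set[tuple[str, str]] = set()
    undirected: set[frozenset] = set(cimap.edges)

    triples = []
    for z in sorted(cimap.nodes):
        nbrs = sorted(adj[z])
        for x, y in itertools.combinations(nbrs, 2):
            if y not in adj[x]:
                triples.append((x, z, y))
    triples.sort()
    for x, z, y in triples:
        pair = frozenset((x, y))
        if pair not in cimap.sepsets:
            raise KeyError(
                f"no separating set recorded for non-adjacent pair "
                f"({x}, {y})"
            )
        if z in cimap.sepsets[pair]:
            continue
        for tail in (x, y):
            e = frozenset((tail, z))
            # a previously fixed opposite direction wins (first processed),
            # and an orientation closing a directed cycle is skipped so the
            # directed part stays acyclic even under inconsistent sepsets
            if e in undirected and not _creates_cycle(directed, tail, z):
                undirected.discard(e)
                directed.add((tail, z))
    return PDAG(tuple(cimap.nodes), directed, undirected)


def _creates_cycle(directed: set[tuple[str, str]], a: str, b: str) -> bool:
    """Would adding a->b close a directed cycle? (DFS from b looking for a)"""
    succ: dict[str, list[str]] = {}
    for u, v in directed:
        succ.setdefault(u, []).append(v)
    stack = [b]
    seen = {b}
    while stack:
        node = stack.pop()
        if node == a:
            return True
        for nxt in succ.get(node, ()):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return False


def rule_closure(pdag: PDAG) -> PDAG:
    """Apply the four standard orientation rules to a fixpoint.

    R1: a->b, b-c, a and c non-adjacent            =>  b->c
    R2: a->b, b->c, a-c                            =>  a->c
    R3: a-b, a-c, a-d, c->b, d->b, c,d non-adjacent =>  a->b
    R4: a-b, a-c, c->d, d->b, b,c non-adjacent,
        a and d adjacent                            =>  a->b

    An orientation that would close a directed cycle is skipped, so the
    directed part stays acyclic for arbitrary input PDAGs.
    """
    p = pdag.copy()
    directed = p.directed
    undirected = p.undirected

    def orient(a: str, b: str) -> bool:
        e = frozenset((a, b))
        if e not in undirected or _creates_cycle(directed, a, b):
            return False
        undirected.discard(e)
        directed.add((a, b))
        return True

    changed = True
    while changed:
        changed = False
        for e in sorted(undirected, key=lambda s: tuple(sorted(s))):
            x, y = sorted(e)
            for a, b in ((x, y), (y, x)):
                # R1
                if any(
                    (c, a) in directed and not p.adjacent(c, b)
                    for c in p.nodes
                ):
                    if orient(a, b):
                        changed = True
                        break
                # R2
                if any(
                    (a, c) in directed and (c, b) in directed
                    for c in p.nodes
                ):
                    if orient(a, b):
                        changed = True
                        break
                # R3
                r3 = False
                for c, d in itertools.combinations(sorted(p.nodes), 2):
                    if (
                        frozenset((a, c)) in undirected
                        and frozenset((a, d)) in undirected
                        and (c, b) in directed
                        and (d, b) in directed
                        and not p.adjacent(c, d)
                    ):
                        r3 = orient(a, b)
                        break
                if r3:
                    changed = True
                    break
                # R4
                r4 = False
                for c in sorted(p.nodes):
                    if frozenset((a, c)) not in undirected:
                        continue
                    if p.adjacent(b, c):
                        continue
                    for d in sorted(p.nodes):
                        if (
                            (c, d) in directed
                            and (d, b) in directed
                            and p.adjacent(a, d)
                        ):
                            r4 = orient(a, b)
                            break
                    if r4:
                        break
                if r4:
                    changed = True
                    break
            if changed:
                break
    return p


def _node_order(
    pdag: PDAG, policy: OrderPolicy, mi_weight: dict[frozenset, float]
) -> list[str]:
    nodes = sorted(pdag.nodes)
    if policy.kind == "random":
        rng = np.random.default_rng(policy.seed)
        return [nodes[i] for i in rng.permutation(len(nodes))]
    avg = {}
    for n in nodes:
        ws = [
            mi_weight.get(e, 0.0)
            for e in pdag.skeleton()
            if n in e
        ]
        avg[n] = float(np.mean(ws)) if ws else 0.0
    reverse = policy.kind == "TSF"
    return sorted(nodes, key=lambda n: ((-avg[n]) if reverse else avg[n], n))


def extend_to_dag(
    pdag: PDAG,
    policy: OrderPolicy,
    mi_weight: dict[frozenset, float] | None = None,
    order: list[str] | None = None,
) -> nx.DiGraph:
    """Orient every undirected edge by sweeping nodes in the policy order,
    pointing edges away from the current node toward not-yet-processed
    neighbours; an orientation closing a directed cycle is reversed.

    ``order`` overrides the policy with an explicit node sequence (used for
    exhaustive enumeration over node orders).
    """
    mi_weight = mi_weight or {}
    if order is not None:
        if sorted(order) != sorted(pdag.nodes):
            raise ValueError("explicit order must be a permutation of nodes")
        order = list(order)
    else:
        order = _node_order(pdag, policy, mi_weight)
    pos = {n: i for i, n in enumerate(order)}
    directed = set(pdag.directed)
    undirected = set(pdag.undirected)
    for u in order:
        nbrs = sorted(
            (v for e in undirected if u in e for v in e if v != u),
            key=lambda v: pos[v],
        )
        for v in nbrs:
            e = frozenset((u, v))
            if e not in undirected:
                continue
            undirected.discard(e)
            if _creates_cycle(directed, u, v):
                directed.add((v, u))
            else:
                directed.add((u, v))
    g = nx.DiGraph()
    g.add_nodes_from(pdag.nodes)
    g.add_edges_from(directed)
    g.graph["order"] = tuple(order)
    return g


def bic_score(dag: nx.DiGraph, data: DiscreteDataset) -> float:
    """Penalised maximum-likelihood score of a DAG structure (higher is
    better; always <= 0).  Zero-count parent configurations contribute 0."""
    if data.n < 1:
        raise ValueError("empty dataset")
    if not set(dag.nodes) <= set(data.names):
        raise ValueError("DAG nodes must be dataset variables")
    n = data.n
    loglik = 0.0
    dim = 0
    for node in dag.nodes:
        parents = sorted(dag.predecessors(node))
        card = data.cardinality(node)
        pcards = [data.cardinality(p) for p in parents]
        dim += (card - 1) * int(np.prod(pcards)) if parents else card - 1
        if parents:
            cfg = np.ravel_multi_index(
                tuple(data.column(p) for p in parents), pcards
            )
        else:
            cfg = np.zeros(n, dtype=np.int64)
        n_cfg = int(np.prod(pcards)) if parents else 1
        joint = np.bincount(
            cfg * card + data.column(node), minlength=n_cfg * card
        ).reshape(n_cfg, card)
        margin = joint.sum(axis=1, keepdims=True)
        mask = joint > 0
        loglik += float(
            np.sum(
                joint[mask]
                * np.log(joint[mask] / np.broadcast_to(margin, joint.shape)[mask])
            )
        )
    return loglik - math.log(n) / 2.0 * dim


def cimap_to_dag(
    cimap: CIMap,
    data: DiscreteDataset,
    max_iter: int = 100,
    seed: int = 0,
) -> ScoredDag:
    """Strongest-first baseline plus ``max_iter`` random-order restarts,
    returning the best-scoring DAG (never worse than the baseline)."""
    if max_iter < 0:
        raise ValueError("max_iter must be >= 0")
    pdag = rule_closure(orient_v_structures(cimap))
    dag = extend_to_dag(pdag, OrderPolicy("TSF"), cimap.mi_weight)
    best = ScoredDag(dag, bic_score(dag, data), dag.graph["order"], "TSF")
    rng = np.random.default_rng(seed)
    for _ in range(max_iter):
        sub = int(rng.integers(0, 2**31 - 1))
        cand = extend_to_dag(
            pdag, OrderPolicy("random", seed=sub), cimap.mi_weight
        )
        score = bic_score(cand, data)
        if score > best.bic:
            best = ScoredDag(cand, score, cand.graph["order"], "random")
    return best
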