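"""PC adjacency search producing a conditional-independence map (CI-map).

The search starts from the fully connected undirected graph and removes an
edge as soon as some conditioning set renders its endpoints independent,
growing the conditioning-set size level by level.  Edges are processed
weakest-first (TWF): candidate edges at each level are visited in ascending
order of their unconditional mutual information, and conditioning subsets are
enumerated in the lexicographic order of the weakest-first node ranking.
All orderings derive from data statistics and variable names only, so the
output does not depend on the column order of the input.

False discoveries of dependence are controlled by a Benjamini-Hochberg
step-up pass over per-edge p-values, on one of three schedules:

* ``basic``       -- one pass after the PC search has converged;
* ``interleaved`` -- a pass after each conditioning-set size;
* ``mini``        -- individual tests never prune; only the per-level
                     step-up pass removes edges.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np

from .bn import DiscreteDataset
from .independence import (
    FnrConfig,
    INDEPENDENT,
    ci_test,
    contingency,
    mutual_information,
)

__all__ = [
    "CIMap",
    "FdrPolicy",
    "twf_node_order",
    "learn_skeleton",
    "apply_fdr",
    "benjamini_hochberg",
]

Edge = frozenset


@dataclass(frozen=True)
class FdrPolicy:
    kind: str = "basic"

    def __post_init__(self) -> None:
        if self.kind not in ("basic", "interleaved", "mini"):
            raise ValueError(
                "FDR policy must be one of basic, interleaved, mini"
            )


@dataclass
class CIMap:
    """Undirected CI-map: edges weighted by unconditional MI, with the
    separating set recorded for every pruned pair."""

    nodes: tuple[str, ...]
    edges: set[frozenset]
    mi_weight: dict[frozenset, float]
    sepsets: dict[frozenset, tuple[str, ...]]
    alpha: float
    policy_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for e in self.edges:
            if e not in self.mi_weight:
                raise ValueError("every edge needs an MI weight")
        for pair, sep in self.sepsets.items():
            if pair in self.edges:
                raise ValueError("sepsets may only key non-adjacent pairs")
            if set(sep) & set(pair):
                raise ValueError("a sepset cannot contain its own pair")

    def adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for e in self.edges:
            a, b = sorted(e)
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def neighbors(self, node: str) -> set[str]:
        return self.adjacency()[node]

    def has_edge(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.edges

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            a, b = sorted(e)
            g.add_edge(a, b, mi=self.mi_weight[e])
        return g

    def to_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)

    def sidecar_json(self) -> str:
        """Sepsets and the policy log, JSON-serialised."""
        return json.dumps(
            {
                "alpha": self.alpha,
                "policy_log": self.policy_log,
                "sepsets": {
                    "|".join(sorted(pair)): sorted(sep)
                    for pair, sep in self.sepsets.items()
                },
            },
            indent=2,
            sort_keys=True,
        )


def _pairwise_mi(data: DiscreteDataset) -> dict[frozenset, float]:
    names = sorted(data.names)
    out: dict[frozenset, float] = {}
    for a, b in itertools.combinations(names, 2):
        out[frozenset((a, b))] = mutual_information(contingency(data, a, b))
    return out


def twf_node_order(data: DiscreteDataset) -> list[str]:
    """Nodes sorted ascending by average pairwise unconditional MI (the
    weakest first), ties broken by name."""
    if len(data.names) < 2:
        raise ValueError("need at least two variables")
    mi = _pairwise_mi(data)
    names = sorted(data.names)
    avg = {
        n: float(
            np.mean([mi[frozenset((n, m))] for m in names if m != n])
        )
        for n in names
    }
    return sorted(names, key=lambda n: (avg[n], n))


def benjamini_hochberg(pvalues: dict, alpha: float) -> set:
    """BH step-up treating small p (dependence) as the discovery; returns
    the discovered keys."""
    if not pvalues:
        return set()
    items = sorted(pvalues.items(), key=lambda kv: kv[1])
    m = len(items)
    k_star = 0
    for k, (_, p) in enumerate(items, start=1):
        if p <= k * alpha / m:
            k_star = k
    return {key for key, _ in items[:k_star]}


def apply_fdr(
    pruning_record: dict, alpha: float, kind: FdrPolicy | str = "basic"
) -> tuple[set, set]:
    """BH step-up over per-edge p-values; returns (kept, pruned) edges.

    The schedule (when this pass runs) is owned by :func:`learn_skeleton`;
    the step-up arithmetic is identical for all three policies.
    """
    if isinstance(kind, FdrPolicy):
        kind = kind.kind
    FdrPolicy(kind)  # validate
    discovered = benjamini_hochberg(pruning_record, alpha)
    return discovered, set(pruning_record) - discovered


def learn_skeleton(
    data: DiscreteDataset,
    alpha: float = 0.05,
    fdr: FdrPolicy | str | None = "basic",
    fnr: FnrConfig | None = None,
    max_level: int | None = None,
) -> CIMap:
    """Level-wise PC search with TWF ordering and an FDR schedule.

    ``fdr=None`` disables the step-up pass entirely (plain PC pruning);
    ``max_level`` optionally caps the conditioning-set size.
    """
    names = sorted(data.names)
    if len(names) < 2:
        raise ValueError("need at least two variables")
    for name in names:
        if len(np.unique(data.column(name))) < 2:
            raise ValueError(
                f"column {name!r} is constant (one observed category)"
            )
    if isinstance(fdr, str):
        fdr = FdrPolicy(fdr)
    kind = fdr.kind if fdr is not None else None

    mi0 = _pairwise_mi(data)
    avg_mi = {
        n: float(
            np.mean([mi0[frozenset((n, m))] for m in names if m != n])
        )
        for n in names
    }
    twf_rank = {
        n: i
        for i, n in enumerate(sorted(names, key=lambda n: (avg_mi[n], n)))
    }

    adj: dict[str, set[str]] = {
        n: {m for m in names if m != n} for n in names
    }
    sepsets: dict[frozenset, tuple[str, ...]] = {}
    # per-edge worst (largest) p among performed tests, with its cond set
    p_max: dict[frozenset, tuple[float, tuple[str, ...]]] = {}
    n_performed = 0
    n_skipped = 0

    def remove(edge: frozenset, sep: tuple[str, ...]) -> None:
        a, b = sorted(edge)
        adj[a].discard(b)
        adj[b].discard(a)
        sepsets[edge] = tuple(sorted(sep))

    def current_edges() -> list[frozenset]:
        return [
            frozenset((a, b))
            for a, b in itertools.combinations(names, 2)
            if b in adj[a]
        ]

    def fdr_pass() -> None:
        record = {
            e: p_max[e][0] for e in current_edges() if e in p_max
        }
        kept, pruned = apply_fdr(record, alpha, kind)
        for e in pruned:
            remove(e, p_max[e][1])

    level = 0
    while True:
        if max_level is not None and level > max_level:
            break
        edges = current_edges()
        feasible = [
            e
            for e in edges
            if any(len(adj[v] - e) >= level for v in e)
        ]
        if not feasible and level > 0:
            break
        # weakest edges first, ties by name pair
        for edge in sorted(
            feasible, key=lambda e: (mi0[e], tuple(sorted(e)))
        ):
            a, b = sorted(edge)
            if b not in adj[a]:
                continue  # pruned earlier at this level
            seen: set[tuple[str, ...]] = set()
            done = False
            for u, v in ((a, b), (b, a)):
                pool = sorted(adj[u] - {v}, key=lambda n: twf_rank[n])
                if len(pool) < level:
                    continue
                for subset in itertools.combinations(pool, level):
                    key = tuple(sorted(subset))
                    if key in seen:
                        continue
                    seen.add(key)
                    res = ci_test(data, a, b, key, alpha=alpha, fnr=fnr)
                    if res.performed:
                        n_performed += 1
                        prev = p_max.get(edge)
                        if prev is None or res.p_value > prev[0]:
                            p_max[edge] = (res.p_value, key)
                        if res.verdict == INDEPENDENT and kind != "mini":
                            remove(edge, key)
                            done = True
                            break
                    else:
                        n_skipped += 1
                if done:
                    break
        if kind in ("interleaved", "mini"):
            fdr_pass()
        level += 1
        if not any(len(adj[n]) - 1 >= level for n in names):
            break
    if kind == "basic":
        fdr_pass()

    edges = set(current_edges())
    return CIMap(
        nodes=tuple(names),
        edges=edges,
        mi_weight={e: mi0[e] for e in edges},
        sepsets=sepsets,
        alpha=alpha,
        policy_log={
            "fdr": kind,
            "fnr": None
            if fnr is None or not fnr.enabled
            else {
                "alpha": fnr.alpha,
                "beta": fnr.beta,
                "effect_size": fnr.effect_size,
            },
            "tests_performed": n_performed,
            "tests_skipped": n_skipped,
            "max_level_reached": level,
        },
    )
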