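"""Bootstrap stability selection of CI-maps around a target variable.

The dataset is resampled with replacement (N-out-of-N) B times, a CI-map is
learned from every replicate, and each non-target node is tallied by how
often it sits at graph distance exactly 1 (first order) or exactly 2 (second
order) from the target.  A hierarchical filter then walks the most frequent
first-order connections (then second order, and so on) and keeps only the
maps exhibiting them, until a single map -- the most representative of the
collection -- survives.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np

from .bn import DiscreteDataset
from .independence import FnrConfig
from .skeleton import CIMap, FdrPolicy, learn_skeleton

__all__ = [
    "AssociationHistogram",
    "FilterConfig",
    "bootstrap_cimaps",
    "association_histogram",
    "hierarchical_filter",
    "most_representative_cimap",
]


@dataclass
class AssociationHistogram:
    """Per-node first/second-order connection frequencies to a target."""

    target: str
    first_order: dict[str, float]   # node -> % of maps adjacent to target
    second_order: dict[str, float]  # node -> % of maps at distance exactly 2
    n_maps: int

    def top_first_order(self) -> str | None:
        """Most frequent first-order node (ties broken by name)."""
        nz = {n: p for n, p in self.first_order.items() if p > 0}
        if not nz:
            return None
        return min(nz, key=lambda n: (-nz[n], n))

    def to_dataframe(self):
        import pandas as pd

        nodes = sorted(self.first_order)
        return pd.DataFrame(
            {
                "node": nodes,
                "first_order_pct": [self.first_order[n] for n in nodes],
                "second_order_pct": [self.second_order[n] for n in nodes],
            }
        )


@dataclass(frozen=True)
class FilterConfig:
    min_freq: float = 0.10
    max_order: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.min_freq < 1:
            raise ValueError("min_freq must lie in [0, 1)")
        if self.max_order < 1:
            raise ValueError("max_order must be >= 1")


def _distances_from(cimap: CIMap, source: str) -> dict[str, int]:
    """Unweighted BFS distances from ``source`` over the CI-map."""
    adj = cimap.adjacency()
    dist = {source: 0}
    queue = deque([source])
    while queue:
        node = queue.popleft()
        for nbr in adj[node]:
            if nbr not in dist:
                dist[nbr] = dist[node] + 1
                queue.append(nbr)
    return dist


def bootstrap_cimaps(
    data: DiscreteDataset,
    b: int,
    alpha: float = 0.05,
    fdr: FdrPolicy | str | None = "basic",
    fnr: FnrConfig | None = None,
    seed: int = 0,
) -> list[CIMap]:
    """Learn one CI-map per N-out-of-N bootstrap replicate (deterministic
    per seed; resample row indices recorded in each map's policy log)."""
    if b < 1:
        raise ValueError("b must be >= 1")
    maps: list[CIMap] = []
    for i, child in enumerate(np.random.SeedSequence(seed).spawn(b)):
        rng = np.random.default_rng(child)
        rows = rng.integers(0, data.n, size=data.n)
        replicate = DiscreteDataset(list(data.variables), data.data[rows])
        try:
            cimap = learn_skeleton(replicate, alpha=alpha, fdr=fdr, fnr=fnr)
        except ValueError as exc:
            raise ValueError(f"bootstrap replicate {i}: {exc}") from exc
        cimap.policy_log["bootstrap_replicate"] = i
        cimap.policy_log["resample_rows"] = rows.tolist()
        maps.append(cimap)
    return maps


def association_histogram(
    maps: list[CIMap], target: str
) -> AssociationHistogram:
    if not maps:
        raise ValueError("need at least one map")
    for m in maps:
        if target not in m.nodes:
            raise KeyError(f"target {target!r} not present in every map")
    nodes = sorted(set(maps[0].nodes) - {target})
    first = dict.fromkeys(nodes, 0)
    second = dict.fromkeys(nodes, 0)
    for m in maps:
        dist = _distances_from(m, target)
        for n in nodes:
            d = dist.get(n)
            if d == 1:
                first[n] += 1
            elif d == 2:
                second[n] += 1
    b = len(maps)
    return AssociationHistogram(
        target=target,
        first_order={n: 100.0 * first[n] / b for n in nodes},
        second_order={n: 100.0 * second[n] / b for n in nodes},
        n_maps=b,
    )


def _order_freq(
    maps: list[CIMap], target: str, order: int
) -> dict[str, float]:
    """Fraction of maps in which each node sits at distance exactly
    ``order`` from the target."""
    nodes = sorted(set(maps[0].nodes) - {target})
    count = dict.fromkeys(nodes, 0)
    for m in maps:
        dist = _distances_from(m, target)
        for n in nodes:
            if dist.get(n) == order:
                count[n] += 1
    return {n: count[n] / len(maps) for n in nodes}


def hierarchical_filter(
    maps: list[CIMap],
    target: str,
    cfg: FilterConfig = FilterConfig(),
) -> CIMap:
    """Keep only the maps exhibiting the most frequent target connections,
    order by order, until one map remains or the rest share the same edge
    set; ties in frequency break lexicographically by node name.

    If no node reaches ``min_freq`` at the very first step, the modal map by
    exact edge-set equality is returned with a warning.
    """
    if not maps:
        raise ValueError("need at least one map")
    survivors = list(maps)

    def all_equal(ms: list[CIMap]) -> bool:
        return all(m.edges == ms[0].edges for m in ms[1:])

    first_step = True
    for order in range(1, cfg.max_order + 1):
        used: set[str] = set()
        while len(survivors) > 1 and not all_equal(survivors):
            freq = _order_freq(survivors, target, order)
            # a node at 100% cannot discriminate; skip it
            candidates = {
                n: f
                for n, f in freq.items()
                if n not in used and f >= cfg.min_freq and 0.0 < f < 1.0
            }
            if not candidates:
                break
            node = min(candidates, key=lambda n: (-candidates[n], n))
            used.add(node)
            survivors = [
                m
                for m in survivors
                if _distances_from(m, target).get(node) == order
            ]
            if first_step:
                first_step = False
        if len(survivors) == 1 or all_equal(survivors):
            break

    if first_step and not all_equal(survivors):
        # the filter never fired: no sufficiently prevalent connection
        warnings.warn(
            "no target connection reaches min_freq; returning the modal map",
            stacklevel=2,
        )
        keys = [frozenset(m.edges) for m in maps]
        counts = {k: keys.count(k) for k in set(keys)}
        modal = max(counts.values())
        for m, k in zip(maps, keys):
            if counts[k] == modal:
                return m
    return survivors[0]


def most_representative_cimap(
    data: DiscreteDataset,
    target: str,
    max_iter: int = 400,
    alpha: float = 0.05,
    fdr: FdrPolicy | str | None = "basic",
    fnr: FnrConfig | None = None,
    seed: int = 0,
    filter_cfg: FilterConfig = FilterConfig(),
) -> CIMap:
    """Bootstrap ``max_iter`` CI-maps, build the association histogram around
    ``target`` and return the hierarchically filtered survivor."""
    if target not in data.names:
        raise KeyError(f"target {target!r} is not a dataset column")
    maps = bootstrap_cimaps(
        data, b=max_iter, alpha=alpha, fdr=fdr, fnr=fnr, seed=seed
    )
    return hierarchical_filter(maps, target, filter_cfg)
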