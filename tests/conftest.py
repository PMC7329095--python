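"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

from cimaps.bn import (
    BayesianNetwork,
    CategoricalVariable,
    ConditionalProbabilityTable,
    DiscreteDataset,
    demo_network,
    forward_sample,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# fixture networks
# ---------------------------------------------------------------------------


def make_chain(p_a=0.5, p_b_given_a=(0.9, 0.1), p_c_given_b=(0.85, 0.2)):
    """A -> B -> C with binary variables and strong links."""
    b2 = ("no", "yes")
    variables = [
        CategoricalVariable("A", b2),
        CategoricalVariable("B", b2),
        CategoricalVariable("C", b2),
    ]
    cpts = {
        "A": ConditionalProbabilityTable("A", (), {(): np.array([p_a, 1 - p_a])}),
        "B": ConditionalProbabilityTable(
            "B", ("A",),
            {(0,): np.array([p_b_given_a[0], 1 - p_b_given_a[0]]),
             (1,): np.array([p_b_given_a[1], 1 - p_b_given_a[1]])},
        ),
        "C": ConditionalProbabilityTable(
            "C", ("B",),
            {(0,): np.array([p_c_given_b[0], 1 - p_c_given_b[0]]),
             (1,): np.array([p_c_given_b[1], 1 - p_c_given_b[1]])},
        ),
    }
    return BayesianNetwork(variables, cpts)


@pytest.fixture(scope="session")
def chain_bn():
    return make_chain()


@pytest.fixture(scope="session")
def chain_data(chain_bn):
    return forward_sample(chain_bn, 5000, seed=11)


@pytest.fixture(scope="session")
def demo_bn():
    return demo_network()


@pytest.fixture(scope="session")
def demo_data(demo_bn):
    return forward_sample(demo_bn, 2000, seed=5)


def random_dataset(rng, n, cards):
    """Uniform random categorical dataset (columns independent)."""
    variables = [
        CategoricalVariable(f"V{j}", tuple(f"c{k}" for k in range(c)))
        for j, c in enumerate(cards)
    ]
    data = np.column_stack([rng.integers(0, c, size=n) for c in cards])
    return DiscreteDataset(variables, data)


# ---------------------------------------------------------------------------
# orientation oracles: exhaustive enumeration on small graphs
# ---------------------------------------------------------------------------


def dag_sepsets(dag: nx.DiGraph) -> dict[frozenset, tuple[str, ...]]:
    """For every non-adjacent pair, the first (smallest, lexicographically
    earliest) subset of the remaining nodes that d-separates it."""
    nodes = sorted(dag.nodes)
    out = {}
    adj = {frozenset(e) for e in dag.edges}
    for x, y in itertools.combinations(nodes, 2):
        if frozenset((x, y)) in adj:
            continue
        rest = [n for n in nodes if n not in (x, y)]
        found = None
        for r in range(len(rest) + 1):
            for sub in itertools.combinations(rest, r):
                if nx.is_d_separator(dag, {x}, {y}, set(sub)):
                    found = sub
                    break
            if found is not None:
                break
        assert found is not None, "DAG pairs are always separable or adjacent"
        out[frozenset((x, y))] = found
    return out


def unshielded_colliders(
    edges: set[tuple[str, str]], skeleton: set[frozenset]
) -> set[tuple[str, str, str]]:
    parents: dict[str, set[str]] = {}
    for a, b in edges:
        parents.setdefault(b, set()).add(a)
    out = set()
    for z, ps in parents.items():
        for x, y in itertools.combinations(sorted(ps), 2):
            if frozenset((x, y)) not in skeleton:
                out.add((x, z, y))
    return out


def consistent_dags(skeleton, sepsets):
    """All acyclic orientations of ``skeleton`` whose unshielded-collider
    pattern matches the sepsets (collider at z iff z outside sepset)."""
    edges = sorted(tuple(sorted(e)) for e in skeleton)
    required = set()
    forbidden = set()
    nodes = sorted({n for e in skeleton for n in e})
    for z in nodes:
        nbrs = sorted(n for n in nodes if frozenset((n, z)) in skeleton)
        for x, y in itertools.combinations(nbrs, 2):
            pair = frozenset((x, y))
            if pair in skeleton:
                continue
            if z in sepsets[pair]:
                forbidden.add((x, z, y))
            else:
                required.add((x, z, y))
    result = []
    for bits in itertools.product((0, 1), repeat=len(edges)):
        directed = {
            (a, b) if bit == 0 else (b, a)
            for (a, b), bit in zip(edges, bits)
        }
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(directed)
        if not nx.is_directed_acyclic_graph(g):
            continue
        coll = unshielded_colliders(directed, skeleton)
        if required <= coll and not (forbidden & coll):
            result.append(directed)
    return result


def oracle_cpdag(skeleton, sepsets):
    """(directed, undirected) edges shared by every consistent DAG."""
    dags = consistent_dags(skeleton, sepsets)
    assert dags, "no consistent orientation exists"
    directed = set.intersection(*(set(d) for d in dags))
    undirected = {
        e for e in skeleton
        if not any(tuple(sorted(e)) in ((a, b), (b, a)) and True
                   for a, b in directed
                   if frozenset((a, b)) == e)
    }
    undirected = {e for e in skeleton
                  if not any(frozenset(d) == e for d in directed)}
    return directed, undirected


def random_dag(rng, n_nodes: int, p_edge: float) -> nx.DiGraph:
    """Random DAG: seeded skeleton + orientation along a random permutation."""
    nodes = [f"N{i}" for i in range(n_nodes)]
    perm = [nodes[i] for i in rng.permutation(n_nodes)]
    pos = {n: i for i, n in enumerate(perm)}
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for a, b in itertools.combinations(nodes, 2):
        if rng.random() < p_edge:
            g.add_edge(*sorted((a, b), key=lambda n: pos[n]))
    return g
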