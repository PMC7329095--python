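"""V-structures, Meek-rule closure, DAG extension and BIC scoring, checked
against exhaustive enumeration oracles on small graphs."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from cimaps.bn import (
    CategoricalVariable,
    DiscreteDataset,
    forward_sample,
    identifiable_random_network,
)
from cimaps.orientation import (
    OrderPolicy,
    PDAG,
    bic_score,
    cimap_to_dag,
    extend_to_dag,
    orient_v_structures,
    rule_closure,
)
from cimaps.skeleton import CIMap, learn_skeleton
from tests.conftest import (
    consistent_dags,
    dag_sepsets,
    oracle_cpdag,
    random_dag,
)


def cimap_from_dag(dag: nx.DiGraph) -> CIMap:
    """Oracle CI-map: the DAG's skeleton plus d-separation sepsets."""
    skel = {frozenset(e) for e in dag.edges}
    return CIMap(
        nodes=tuple(sorted(dag.nodes)),
        edges=set(skel),
        mi_weight=dict.fromkeys(skel, 0.1),
        sepsets=dag_sepsets(dag),
        alpha=0.05,
    )


# ---------------------------------------------------------------------------
# PDAG / OrderPolicy validation
# ---------------------------------------------------------------------------


def test_pdag_rejects_overlap_and_cycles():
    with pytest.raises(ValueError):
        PDAG(("a", "b"), {("a", "b")}, {frozenset(("a", "b"))})
    with pytest.raises(ValueError, match="cycle"):
        PDAG(("a", "b", "c"), {("a", "b"), ("b", "c"), ("c", "a")}, set())


def test_order_policy_validation():
    with pytest.raises(ValueError):
        OrderPolicy("bogus")
    with pytest.raises(ValueError):
        OrderPolicy("random")  # missing seed
    with pytest.raises(ValueError):
        OrderPolicy("TSF", seed=1)  # spurious seed


# ---------------------------------------------------------------------------
# v-structures
# ---------------------------------------------------------------------------


def test_collider_oriented():
    g = nx.DiGraph([("A", "C"), ("B", "C")])
    pdag = orient_v_structures(cimap_from_dag(g))
    assert pdag.directed == {("A", "C"), ("B", "C")}
    assert pdag.undirected == set()


def test_chain_not_oriented():
    g = nx.DiGraph([("A", "B"), ("B", "C")])
    pdag = orient_v_structures(cimap_from_dag(g))
    assert pdag.directed == set()
    assert pdag.undirected == {frozenset(("A", "B")), frozenset(("B", "C"))}


def test_shielded_triple_not_oriented():
    g = nx.DiGraph([("A", "C"), ("B", "C"), ("A", "B")])
    pdag = orient_v_structures(cimap_from_dag(g))
    assert pdag.directed == set()


def test_missing_sepset_raises():
    cimap = CIMap(
        nodes=("A", "B", "C"),
        edges={frozenset(("A", "C")), frozenset(("B", "C"))},
        mi_weight={frozenset(("A", "C")): 0.1, frozenset(("B", "C")): 0.1},
        sepsets={},  # pair (A, B) unrecorded
        alpha=0.05,
    )
    with pytest.raises(KeyError):
        orient_v_structures(cimap)


def test_inconsistent_sepsets_stay_acyclic():
    """Sepsets demanding contradictory colliders must not break the PDAG
    acyclicity invariant."""
    edges = {frozenset(p) for p in
             (("A", "B"), ("B", "C"), ("C", "D"), ("D", "A"))}
    cimap = CIMap(
        nodes=("A", "B", "C", "D"),
        edges=set(edges),
        mi_weight=dict.fromkeys(edges, 0.1),
        sepsets={frozenset(("A", "C")): (), frozenset(("B", "D")): ()},
        alpha=0.05,
    )
    pdag = orient_v_structures(cimap)  # must not raise
    g = nx.DiGraph(list(pdag.directed))
    assert nx.is_directed_acyclic_graph(g)


# ---------------------------------------------------------------------------
# rule closure against the enumeration oracle (CPDAG)
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("seed", range(12))
def test_closure_matches_enumerated_cpdag(seed):
    """After v-structures + rule closure, the directed edges are exactly
    those shared by every consistent DAG, and the undirected ones are
    genuinely reversible."""
    rng = np.random.default_rng(seed)
    dag = random_dag(rng, 5, 0.4)
    if dag.number_of_edges() == 0:
        pytest.skip("empty graph is vacuous")
    skel = {frozenset(e) for e in dag.edges}
    seps = dag_sepsets(dag)
    closed = rule_closure(orient_v_structures(cimap_from_dag(dag)))
    want_dir, want_undir = oracle_cpdag(skel, seps)
    assert closed.directed == want_dir
    assert closed.undirected == want_undir


def test_rule1_chain_propagation():
    """a->b with b-c (a,c non-adjacent) forces b->c."""
    pdag = PDAG(("a", "b", "c"), {("a", "b")}, {frozenset(("b", "c"))})
    closed = rule_closure(pdag)
    assert ("b", "c") in closed.directed


def test_rule2_acyclicity():
    """a->b->c with a-c forces a->c."""
    pdag = PDAG(
        ("a", "b", "c"),
        {("a", "b"), ("b", "c")},
        {frozenset(("a", "c"))},
    )
    closed = rule_closure(pdag)
    assert ("a", "c") in closed.directed


def test_rule3():
    pdag = PDAG(
        ("a", "b", "c", "d"),
        {("c", "b"), ("d", "b")},
        {frozenset(("a", "b")), frozenset(("a", "c")), frozenset(("a", "d"))},
    )
    closed = rule_closure(pdag)
    assert ("a", "b") in closed.directed


# ---------------------------------------------------------------------------
# DAG extension
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("seed", range(8))
def test_extension_is_consistent_dag(seed):
    """Every extension is acyclic, keeps the skeleton, preserves the already
    directed edges and creates no new unshielded collider."""
    rng = np.random.default_rng(100 + seed)
    dag = random_dag(rng, 6, 0.4)
    skel = {frozenset(e) for e in dag.edges}
    if not skel:
        pytest.skip("empty graph")
    closed = rule_closure(orient_v_structures(cimap_from_dag(dag)))
    for policy in (OrderPolicy("TSF"), OrderPolicy("TWF"),
                   OrderPolicy("random", seed=7)):
        ext = extend_to_dag(closed, policy)
        assert nx.is_directed_acyclic_graph(ext)
        assert {frozenset(e) for e in ext.edges} == skel
        assert closed.directed <= set(ext.edges)


def test_extension_explicit_order():
    pdag = PDAG(("a", "b"), set(), {frozenset(("a", "b"))})
    g1 = extend_to_dag(pdag, OrderPolicy("TSF"), order=["a", "b"])
    g2 = extend_to_dag(pdag, OrderPolicy("TSF"), order=["b", "a"])
    assert set(g1.edges) == {("a", "b")}
    assert set(g2.edges) == {("b", "a")}
    with pytest.raises(ValueError):
        extend_to_dag(pdag, OrderPolicy("TSF"), order=["a"])


def test_extension_reverses_on_cycle():
    """Orienting along the order would close a cycle; the edge is reversed."""
    pdag = PDAG(
        ("a", "b", "c"),
        {("b", "c"), ("c", "a")},
        {frozenset(("a", "b"))},
    )
    g = extend_to_dag(pdag, OrderPolicy("TSF"), order=["a", "b", "c"])
    assert nx.is_directed_acyclic_graph(g)
    assert ("b", "a") in g.edges  # a->b would have closed the cycle


# ---------------------------------------------------------------------------
# BIC
# ---------------------------------------------------------------------------


def test_bic_single_node_oracle():
    """One binary node, 100 identical rows: loglik 0, dim 1,
    BIC = -ln(100)/2."""
    v = [CategoricalVariable("A", ("x", "y"))]
    d = DiscreteDataset(v, np.zeros((100, 1), dtype=int))
    g = nx.DiGraph()
    g.add_node("A")
    assert bic_score(g, d) == pytest.approx(-math.log(100) / 2, rel=1e-12)


def test_bic_literal_formula(chain_data):
    """Hand-computed BIC of A -> B on the chain data."""
    g = nx.DiGraph([("A", "B")])
    g.add_node("C")
    a = chain_data.column("A")
    b = chain_data.column("B")
    c = chain_data.column("C")
    n = chain_data.n
    ll = 0.0
    # A and C unconditional, B given A
    for col in (a, c):
        counts = np.bincount(col, minlength=2)
        ll += sum(k * math.log(k / n) for k in counts if k > 0)
    for av in (0, 1):
        sub = b[a == av]
        na = len(sub)
        counts = np.bincount(sub, minlength=2)
        ll += sum(k * math.log(k / na) for k in counts if k > 0)
    dim = 1 + 2 + 1  # A, B|A, C
    expected = ll - math.log(n) / 2 * dim
    assert bic_score(g, chain_data) == pytest.approx(expected, rel=1e-12)


def test_bic_nonpositive_and_markov_equivalent_equal(chain_data):
    g1 = nx.DiGraph([("A", "B"), ("B", "C")])
    g2 = nx.DiGraph([("B", "A"), ("B", "C")])  # same CPDAG
    s1, s2 = bic_score(g1, chain_data), bic_score(g2, chain_data)
    assert s1 <= 0 and s2 <= 0
    assert s1 == pytest.approx(s2, rel=1e-12)


def test_bic_prefers_true_structure(chain_data):
    chain = nx.DiGraph([("A", "B"), ("B", "C")])
    collider = nx.DiGraph([("A", "B"), ("C", "B")])  # wrong CPDAG
    assert bic_score(chain, chain_data) > bic_score(collider, chain_data)


# ---------------------------------------------------------------------------
# cimap_to_dag: search quality
# ---------------------------------------------------------------------------


def test_cimap_to_dag_beats_or_matches_tsf(demo_data):
    cimap = learn_skeleton(demo_data, alpha=0.01)
    pdag = rule_closure(orient_v_structures(cimap))
    tsf = extend_to_dag(pdag, OrderPolicy("TSF"), cimap.mi_weight)
    tsf_bic = bic_score(tsf, demo_data)
    best = cimap_to_dag(cimap, demo_data, max_iter=50, seed=0)
    assert best.bic >= tsf_bic
    assert nx.is_directed_acyclic_graph(best.dag)
    assert {frozenset(e) for e in best.dag.edges} == cimap.edges


def test_cimap_to_dag_finds_exhaustive_optimum():
    """With enough restarts the search attains the best BIC over all 120
    node orders of a 5-node map."""
    bn = identifiable_random_network(5, 2, (2, 3), seed=11)
    data = forward_sample(bn, 5000, seed=3)
    cimap = learn_skeleton(data, alpha=0.01)
    pdag = rule_closure(orient_v_structures(cimap))
    best_exhaustive = -math.inf
    for perm in itertools.permutations(sorted(cimap.nodes)):
        g = extend_to_dag(pdag, OrderPolicy("TSF"), order=list(perm))
        best_exhaustive = max(best_exhaustive, bic_score(g, data))
    found = cimap_to_dag(cimap, data, max_iter=2000, seed=1)
    assert found.bic == pytest.approx(best_exhaustive, rel=1e-12)


def test_cimap_to_dag_deterministic(demo_data):
    cimap = learn_skeleton(demo_data, alpha=0.01)
    a = cimap_to_dag(cimap, demo_data, max_iter=20, seed=5)
    b = cimap_to_dag(cimap, demo_data, max_iter=20, seed=5)
    assert set(a.dag.edges) == set(b.dag.edges)
    assert a.bic == b.bic


def test_scored_dag_to_dot(demo_data):
    cimap = learn_skeleton(demo_data, alpha=0.01)
    dot = cimap_to_dag(cimap, demo_data, max_iter=5, seed=0).to_dot()
    assert dot.startswith("digraph")
    assert "->" in dot
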