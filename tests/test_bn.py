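"""Bayesian-network representation, BIF I/O, sampling, stats, fixtures."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cimaps.bn import (
    BayesianNetwork,
    CategoricalVariable,
    ConditionalProbabilityTable,
    DiscreteDataset,
    demo_network,
    exact_joint,
    exact_conditional_mi,
    forward_sample,
    identifiable_random_network,
    network_stats,
    random_network,
    read_bif,
    write_bif,
)
from tests.conftest import make_chain


# ---------------------------------------------------------------------------
# representation / validation
# ---------------------------------------------------------------------------


def test_variable_validation():
    with pytest.raises(ValueError):
        CategoricalVariable("X", ("only",))
    with pytest.raises(ValueError):
        CategoricalVariable("X", ("a", "a"))
    with pytest.raises(ValueError):
        CategoricalVariable("", ("a", "b"))


def test_cpt_row_not_summing_to_one_rejected():
    v = [CategoricalVariable("A", ("x", "y"))]
    cpt = ConditionalProbabilityTable("A", (), {(): np.array([0.6, 0.6])})
    with pytest.raises(ValueError, match="sums to"):
        BayesianNetwork(v, {"A": cpt})


def test_cpt_row_renormalised_within_tolerance():
    v = [CategoricalVariable("A", ("x", "y"))]
    cpt = ConditionalProbabilityTable(
        "A", (), {(): np.array([0.5 + 2e-7, 0.5])}
    )
    bn = BayesianNetwork(v, {"A": cpt})
    assert abs(float(bn.cpts["A"].table[()].sum()) - 1.0) < 1e-12


def test_cpt_missing_parent_row_rejected():
    v = [
        CategoricalVariable("A", ("x", "y")),
        CategoricalVariable("B", ("x", "y")),
    ]
    cpts = {
        "A": ConditionalProbabilityTable("A", (), {(): np.array([0.5, 0.5])}),
        "B": ConditionalProbabilityTable(
            "B", ("A",), {(0,): np.array([0.5, 0.5])}  # row (1,) missing
        ),
    }
    with pytest.raises(ValueError):
        BayesianNetwork(v, cpts)


def test_cycle_rejected():
    v = [
        CategoricalVariable("A", ("x", "y")),
        CategoricalVariable("B", ("x", "y")),
    ]
    half = np.array([0.5, 0.5])
    cpts = {
        "A": ConditionalProbabilityTable(
            "A", ("B",), {(0,): half, (1,): half}
        ),
        "B": ConditionalProbabilityTable(
            "B", ("A",), {(0,): half, (1,): half}
        ),
    }
    with pytest.raises(ValueError, match="cycle"):
        BayesianNetwork(v, cpts)


def test_topological_order_respects_edges(chain_bn):
    order = chain_bn.topological_order()
    for a, b in chain_bn.edges:
        assert order.index(a) < order.index(b)


def test_skeleton_and_edges(chain_bn):
    assert chain_bn.edges == {("A", "B"), ("B", "C")}
    assert chain_bn.skeleton() == {
        frozenset(("A", "B")),
        frozenset(("B", "C")),
    }


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------


def test_dataset_out_of_range_rejected():
    v = [CategoricalVariable("A", ("x", "y"))]
    with pytest.raises(ValueError, match="out-of-range"):
        DiscreteDataset(v, np.array([[0], [2]]))


def test_dataset_dataframe_roundtrip(chain_data):
    df = chain_data.to_dataframe()
    back = DiscreteDataset.from_dataframe(df)
    assert back.names == chain_data.names
    assert np.array_equal(back.data, chain_data.data)
    # labels, not codes, in the dataframe
    assert set(df["A"].unique()) <= {"no", "yes"}


def test_dataset_select(chain_data):
    sub = chain_data.select(["C", "A"])
    assert sub.names == ["C", "A"]
    assert np.array_equal(sub.column("A"), chain_data.column("A"))


def test_resample_preserves_shape_and_draws_from_rows(chain_data):
    rng = np.random.default_rng(3)
    r = chain_data.resample(rng)
    assert r.n == chain_data.n
    seen = {tuple(row) for row in chain_data.data}
    assert all(tuple(row) in seen for row in r.data[:100])


# ---------------------------------------------------------------------------
# BIF round trip
# ---------------------------------------------------------------------------


def test_bif_roundtrip(tmp_path, demo_bn):
    path = tmp_path / "demo.bif"
    write_bif(demo_bn, path)
    back = read_bif(path)
    assert back.structurally_equal(demo_bn)


def test_bif_roundtrip_random(tmp_path):
    bn = random_network(6, 2, (2, 4), 1.0, seed=42)
    path = tmp_path / "r.bif"
    write_bif(bn, path)
    assert read_bif(path).structurally_equal(bn)


def test_bif_flat_table_and_comments(tmp_path):
    text = """
// line comment
network test { }
variable A {
  type discrete [ 2 ] { x, y };
}
variable B {
  type discrete [ 2 ] { u, v };
}
/* block
   comment */
probability ( A ) {
  table 0.3, 0.7;
}
probability ( B | A ) {
  table 0.1, 0.9, 0.8, 0.2;
}
"""
    p = tmp_path / "t.bif"
    p.write_text(text)
    bn = read_bif(p)
    assert bn.parents("B") == ("A",)
    np.testing.assert_allclose(bn.cpts["B"].table[(0,)], [0.1, 0.9])
    np.testing.assert_allclose(bn.cpts["B"].table[(1,)], [0.8, 0.2])


def test_bif_per_row_clause(tmp_path):
    text = """
variable A { type discrete [ 2 ] { x, y }; }
variable B { type discrete [ 3 ] { p, q, r }; }
probability ( A ) { table 0.4, 0.6; }
probability ( B | A ) {
  ( x ) 0.2, 0.3, 0.5;
  ( y ) 0.6, 0.3, 0.1;
}
"""
    p = tmp_path / "t.bif"
    p.write_text(text)
    bn = read_bif(p)
    np.testing.assert_allclose(bn.cpts["B"].table[(1,)], [0.6, 0.3, 0.1])


def test_bif_bad_probability_sum_rejected(tmp_path):
    text = """
variable A { type discrete [ 2 ] { x, y }; }
probability ( A ) { table 0.5, 0.6; }
"""
    p = tmp_path / "bad.bif"
    p.write_text(text)
    with pytest.raises(ValueError):
        read_bif(p)


def test_bif_missing_cpt_rejected(tmp_path):
    text = """
variable A { type discrete [ 2 ] { x, y }; }
variable B { type discrete [ 2 ] { x, y }; }
probability ( A ) { table 0.5, 0.5; }
"""
    p = tmp_path / "bad.bif"
    p.write_text(text)
    with pytest.raises(ValueError, match="B"):
        read_bif(p)


# ---------------------------------------------------------------------------
# forward sampling
# ---------------------------------------------------------------------------


def test_forward_sample_deterministic(chain_bn):
    a = forward_sample(chain_bn, 500, seed=9)
    b = forward_sample(chain_bn, 500, seed=9)
    c = forward_sample(chain_bn, 500, seed=10)
    assert np.array_equal(a.data, b.data)
    assert not np.array_equal(a.data, c.data)


def test_forward_sample_matches_exact_joint(demo_bn):
    """Empirical cell frequencies converge on the enumerated joint."""
    n = 50_000
    d = forward_sample(demo_bn, n, seed=21)
    joint = exact_joint(demo_bn)
    cards = [v.cardinality for v in demo_bn.variables]
    flat = np.ravel_multi_index(tuple(d.data.T), cards)
    emp = np.bincount(flat, minlength=int(np.prod(cards))) / n
    # max absolute deviation over all 3456 cells: a few sigma of 1/sqrt(n)
    assert np.max(np.abs(emp - joint.ravel())) < 0.01


def test_forward_sample_marginal_of_root(chain_bn):
    d = forward_sample(chain_bn, 20_000, seed=2)
    p_hat = d.column("A").mean()
    assert abs(p_hat - 0.5) < 0.02


# ---------------------------------------------------------------------------
# exact quantities
# ---------------------------------------------------------------------------


def test_exact_joint_sums_to_one(demo_bn):
    assert abs(exact_joint(demo_bn).sum() - 1.0) < 1e-12


def test_exact_conditional_mi_chain(chain_bn):
    """In A -> B -> C: I(A;C) > 0 but I(A;C|B) = 0."""
    assert exact_conditional_mi(chain_bn, "A", "C") > 0.05
    assert exact_conditional_mi(chain_bn, "A", "C", ("B",)) < 1e-12


def test_exact_conditional_mi_collider():
    """In A -> C <- B: I(A;B) = 0 but I(A;B|C) > 0."""
    b2 = ("x", "y")
    v = [CategoricalVariable(n, b2) for n in ("A", "B", "C")]
    half = np.array([0.5, 0.5])
    cpts = {
        "A": ConditionalProbabilityTable("A", (), {(): half}),
        "B": ConditionalProbabilityTable("B", (), {(): half}),
        "C": ConditionalProbabilityTable(
            "C", ("A", "B"),
            {(0, 0): np.array([0.9, 0.1]), (0, 1): np.array([0.3, 0.7]),
             (1, 0): np.array([0.3, 0.7]), (1, 1): np.array([0.9, 0.1])},
        ),
    }
    bn = BayesianNetwork(v, cpts)
    assert exact_conditional_mi(bn, "A", "B") < 1e-12
    assert exact_conditional_mi(bn, "A", "B", ("C",)) > 0.01


# ---------------------------------------------------------------------------
# stats and fixtures
# ---------------------------------------------------------------------------


def test_network_stats_chain(chain_bn):
    s = network_stats(chain_bn)
    assert s.n_nodes == 3
    assert s.n_edges == 2
    # params: A 1, B|A 2, C|B 2
    assert s.n_parameters == 5
    assert s.avg_degree == pytest.approx(4 / 3)
    # blankets: A {B}, B {A, C}, C {B}
    assert s.avg_markov_blanket == pytest.approx(4 / 3)
    assert s.max_in_degree == 1


def test_network_stats_demo(demo_bn):
    s = network_stats(demo_bn)
    assert s.n_nodes == 8
    assert s.n_edges == 9
    assert s.max_in_degree == 2
    assert s.avg_degree == pytest.approx(18 / 8)


def test_random_network_deterministic_and_valid():
    a = random_network(7, 3, (2, 4), 1.0, seed=5)
    b = random_network(7, 3, (2, 4), 1.0, seed=5)
    assert a.structurally_equal(b)
    assert all(len(a.parents(n)) <= 3 for n in a.names)
    assert all(2 <= a.variable(n).cardinality <= 4 for n in a.names)
    a.topological_order()  # acyclic


def test_random_network_invalid_args():
    with pytest.raises(ValueError):
        random_network(3, 3, (2, 3), 1.0, seed=0)
    with pytest.raises(ValueError):
        random_network(3, 1, (1, 3), 1.0, seed=0)
    with pytest.raises(ValueError):
        random_network(3, 1, (2, 3), 0.0, seed=0)


def test_identifiable_random_network_meets_screen():
    bn = identifiable_random_network(4, 2, (2, 3), seed=77)
    for a, b in bn.edges:
        others = [n for n in bn.names if n not in (a, b)]
        for r in range(len(others) + 1):
            for sub in itertools.combinations(others, r):
                assert exact_conditional_mi(bn, a, b, sub) >= 0.01
    joint = exact_joint(bn)
    for j in range(len(bn.names)):
        axes = tuple(k for k in range(len(bn.names)) if k != j)
        assert joint.sum(axis=axes).min() >= 0.05


def test_demo_network_marginals_not_degenerate(demo_bn):
    joint = exact_joint(demo_bn)
    for j in range(8):
        axes = tuple(k for k in range(8) if k != j)
        assert joint.sum(axis=axes).min() > 0.05


@given(st.integers(min_value=0, max_value=10_000))
def test_forward_sample_any_seed_valid(seed):
    d = forward_sample(make_chain(), 50, seed=seed)
    assert d.data.min() >= 0 and d.data.max() <= 1
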