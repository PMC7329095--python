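"""Discrete Bayesian networks: representation, BIF input/output, forward
sampling, descriptive statistics and seeded random fixture generation.

A :class:`BayesianNetwork` is a DAG over categorical variables together with
one conditional probability table (CPT) per variable.  Networks can be read
from and written to the BIF dialect used by the Bayesian Network Repository,
forward-sampled into a :class:`DiscreteDataset`, and summarised with the usual
structural statistics (parameter count, average degree, average Markov-blanket
size, maximum in-degree).
"""

from __future__ import annotations

import itertools
import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CategoricalVariable",
    "ConditionalProbabilityTable",
    "BayesianNetwork",
    "DiscreteDataset",
    "NetworkStats",
    "read_bif",
    "write_bif",
    "forward_sample",
    "network_stats",
    "random_network",
    "demo_network",
]

# |sum - 1| below this is silently accepted; up to _RENORM_TOL the row is
# renormalised (repository files carry rounded decimals); beyond it -> error.
_EXACT_TOL = 1e-9
_RENORM_TOL = 1e-6


class BifFormatError(ValueError):
    """Raised when a BIF file cannot be parsed."""


class ValidationError(ValueError):
    """Raised when a network or dataset violates a structural invariant."""


@dataclass(frozen=True)
class CategoricalVariable:
    """A named variable with an ordered set of category labels."""

    name: str
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("variable name must be non-empty")
        if len(self.categories) < 2:
            raise ValidationError(
                f"variable {self.name!r} needs at least 2 categories"
            )
        if len(set(self.categories)) != len(self.categories):
            raise ValidationError(
                f"variable {self.name!r} has duplicate category labels"
            )

    @property
    def cardinality(self) -> int:
        return len(self.categories)


@dataclass
class ConditionalProbabilityTable:
    """P(child | parents) as a dense mapping from joint parent assignments
    (tuples of parent category indices) to probability vectors."""

    child: str
    parents: tuple[str, ...]
    table: dict[tuple[int, ...], np.ndarray]

    def validate(self, cards: dict[str, int]) -> None:
        expected = list(
            itertools.product(*(range(cards[p]) for p in self.parents))
        )
        if set(self.table) != set(expected):
            raise ValidationError(
                f"CPT for {self.child!r} does not cover every joint parent "
                "assignment exactly once"
            )
        card = cards[self.child]
        for key in expected:
            vec = np.asarray(self.table[key], dtype=float)
            if vec.shape != (card,):
                raise ValidationError(
                    f"CPT row {key} for {self.child!r} has wrong length"
                )
            if (vec < 0).any():
                raise ValidationError(
                    f"CPT row {key} for {self.child!r} has negative entries"
                )
            dev = abs(float(vec.sum()) - 1.0)
            if dev > _RENORM_TOL:
                raise ValidationError(
                    f"CPT row {key} for {self.child!r} sums to {vec.sum():.12g}"
                )
            if dev > _EXACT_TOL:
                vec = vec / vec.sum()
            self.table[key] = vec


@dataclass
class BayesianNetwork:
    """Directed acyclic graph over categorical variables with CPTs."""

    variables: list[CategoricalVariable]
    cpts: dict[str, ConditionalProbabilityTable]

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate variable names")
        self._by_name = {v.name: v for v in self.variables}
        cards = {v.name: v.cardinality for v in self.variables}
        if set(self.cpts) != set(names):
            raise ValidationError("need exactly one CPT per variable")
        for cpt in self.cpts.values():
            for p in cpt.parents:
                if p not in self._by_name:
                    raise ValidationError(
                        f"CPT for {cpt.child!r} references unknown parent {p!r}"
                    )
            cpt.validate(cards)
        self.topological_order()  # raises on cycles

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def variable(self, name: str) -> CategoricalVariable:
        return self._by_name[name]

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {
            (p, cpt.child) for cpt in self.cpts.values() for p in cpt.parents
        }

    def parents(self, name: str) -> tuple[str, ...]:
        return self.cpts[name].parents

    def children(self, name: str) -> list[str]:
        return [c for c in self.names if name in self.cpts[c].parents]

    def skeleton(self) -> set[frozenset[str]]:
        """Undirected edge set."""
        return {frozenset(e) for e in self.edges}

    def topological_order(self) -> list[str]:
        """Kahn's algorithm, ties broken by declaration order."""
        order: list[str] = []
        indeg = {n: len(self.cpts[n].parents) for n in self.names}
        ready = [n for n in self.names if indeg[n] == 0]
        children: dict[str, list[str]] = {n: [] for n in self.names}
        for n in self.names:
            for p in self.cpts[n].parents:
                children[p].append(n)
        while ready:
            node = ready.pop(0)
            order.append(node)
            for c in children[node]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    ready.append(c)
        if len(order) != len(self.names):
            raise ValidationError("edge set contains a directed cycle")
        return order

    def structurally_equal(self, other: "BayesianNetwork") -> bool:
        if self.names != other.names:
            return False
        for v, w in zip(self.variables, other.variables):
            if v != w:
                return False
        for name in self.names:
            a, b = self.cpts[name], other.cpts[name]
            if a.parents != b.parents:
                return False
            for key, vec in a.table.items():
                if not np.allclose(vec, b.table[key], atol=1e-9):
                    return False
        return True


@dataclass
class DiscreteDataset:
    """N rows of category indices over a fixed variable list."""

    variables: list[CategoricalVariable]
    data: np.ndarray  # (N, p) integer category indices

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int64)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.variables):
            raise ValidationError("data shape does not match variable list")
        if self.data.shape[0] < 1:
            raise ValidationError("dataset must have at least one row")
        for j, var in enumerate(self.variables):
            col = self.data[:, j]
            if col.min() < 0 or col.max() >= var.cardinality:
                raise ValidationError(
                    f"column {var.name!r} holds an out-of-range category index"
                )
        self._index = {v.name: j for j, v in enumerate(self.variables)}

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def column(self, name: str) -> np.ndarray:
        return self.data[:, self._index[name]]

    def cardinality(self, name: str) -> int:
        return self.variables[self._index[name]].cardinality

    def select(self, names: list[str]) -> "DiscreteDataset":
        idx = [self._index[n] for n in names]
        return DiscreteDataset(
            [self.variables[i] for i in idx], self.data[:, idx]
        )

    def resample(self, rng: np.random.Generator) -> "DiscreteDataset":
        """N-out-of-N bootstrap resample (rows drawn with replacement)."""
        rows = rng.integers(0, self.n, size=self.n)
        return DiscreteDataset(list(self.variables), self.data[rows])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                v.name: [v.categories[i] for i in self.data[:, j]]
                for j, v in enumerate(self.variables)
            }
        )

    @classmethod
    def from_dataframe(cls, df) -> "DiscreteDataset":
        variables = []
        cols = []
        for name in df.columns:
            values = df[name].astype(str)
            cats = tuple(sorted(values.unique()))
            lookup = {c: i for i, c in enumerate(cats)}
            variables.append(CategoricalVariable(str(name), cats))
            cols.append(values.map(lookup).to_numpy())
        return cls(variables, np.column_stack(cols))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@dataclass(frozen=True)
class NetworkStats:
    n_nodes: int
    n_edges: int
    n_parameters: int
    avg_degree: float
    avg_markov_blanket: float
    max_in_degree: int


# ---------------------------------------------------------------------------
# BIF input/output
# ---------------------------------------------------------------------------

_COMMENT_BLOCK = re.compile(r"/\*.*?\*/", re.S)
_COMMENT_LINE = re.compile(r"//[^\n]*")


def _strip_comments(text: str) -> str:
    return _COMMENT_LINE.sub("", _COMMENT_BLOCK.sub("", text))


def _line_of(text: str, pos: int) -> int:
    return text.count("\n", 0, pos) + 1


def read_bif(path) -> BayesianNetwork:
    """Read a network in the Bayesian Network Repository BIF dialect.

    Accepts ``variable`` blocks with ``type discrete``, unconditional
    ``probability ( X ) { table ...; }`` clauses and conditional clauses with
    either per-parent-assignment rows ``( a, b ) p1, p2;`` or a flat
    ``table`` listing all rows in parent-assignment product order.  Unknown
    ``property`` lines produce a warning, not an error.
    """
    with open(path) as fh:
        raw = fh.read()
    text = _strip_comments(raw)

    variables: list[CategoricalVariable] = []
    cards: dict[str, int] = {}
    cat_index: dict[str, dict[str, int]] = {}

    # the block body may contain one level of nested braces (the category list)
    var_re = re.compile(
        r"variable\s+([\w.\-]+)\s*\{((?:[^{}]|\{[^{}]*\})*)\}", re.S
    )
    type_re = re.compile(
        r"type\s+discrete\s*\[\s*(\d+)\s*\]\s*\{([^}]*)\}", re.S
    )
    for m in var_re.finditer(text):
        name, body = m.group(1), m.group(2)
        tm = type_re.search(body)
        if tm is None:
            raise BifFormatError(
                f"line {_line_of(text, m.start())}: variable {name!r} has no "
                "discrete type declaration"
            )
        n_cat = int(tm.group(1))
        cats = tuple(c.strip() for c in tm.group(2).split(",") if c.strip())
        if len(cats) != n_cat:
            raise BifFormatError(
                f"line {_line_of(text, m.start())}: variable {name!r} "
                f"declares {n_cat} categories but lists {len(cats)}"
            )
        if re.search(r"property", body):
            warnings.warn(
                f"ignoring property lines in variable block {name!r}",
                stacklevel=2,
            )
        variables.append(CategoricalVariable(name, cats))
        cards[name] = n_cat
        cat_index[name] = {c: i for i, c in enumerate(cats)}

    if not variables:
        raise BifFormatError("no variable blocks found")

    cpts: dict[str, ConditionalProbabilityTable] = {}
    prob_re = re.compile(
        r"probability\s*\(\s*([\w.\-]+)\s*(?:\|\s*([\w.\-,\s]+?))?\s*\)"
        r"\s*\{(.*?)\}",
        re.S,
    )
    for m in prob_re.finditer(text):
        child = m.group(1)
        if child not in cards:
            raise BifFormatError(
                f"line {_line_of(text, m.start())}: probability clause for "
                f"undeclared variable {child!r}"
            )
        parents = tuple(
            p.strip() for p in (m.group(2) or "").split(",") if p.strip()
        )
        for p in parents:
            if p not in cards:
                raise BifFormatError(
                    f"line {_line_of(text, m.start())}: undeclared parent "
                    f"{p!r} of {child!r}"
                )
        body = m.group(3)
        table: dict[tuple[int, ...], np.ndarray] = {}

        row_re = re.compile(r"\(([^)]*)\)\s*([^;]+);")
        table_re = re.compile(r"table\s+([^;]+);")
        rows = row_re.findall(body)
        if rows:
            for labels, values in rows:
                key_labels = [s.strip() for s in labels.split(",")]
                if len(key_labels) != len(parents):
                    raise BifFormatError(
                        f"line {_line_of(text, m.start())}: row of {child!r} "
                        f"lists {len(key_labels)} parent values, expected "
                        f"{len(parents)}"
                    )
                try:
                    key = tuple(
                        cat_index[p][lab]
                        for p, lab in zip(parents, key_labels)
                    )
                except KeyError as exc:
                    raise BifFormatError(
                        f"line {_line_of(text, m.start())}: unknown parent "
                        f"category {exc} in a row of {child!r}"
                    ) from None
                table[key] = np.array(
                    [float(v) for v in values.replace(",", " ").split()]
                )
        else:
            tm = table_re.search(body)
            if tm is None:
                raise BifFormatError(
                    f"line {_line_of(text, m.start())}: probability clause "
                    f"for {child!r} has neither rows nor a table"
                )
            flat = [
                float(v) for v in tm.group(1).replace(",", " ").split()
            ]
            keys = list(
                itertools.product(*(range(cards[p]) for p in parents))
            )
            if len(flat) != len(keys) * cards[child]:
                raise BifFormatError(
                    f"line {_line_of(text, m.start())}: table for {child!r} "
                    f"has {len(flat)} entries, expected "
                    f"{len(keys) * cards[child]}"
                )
            for i, key in enumerate(keys):
                table[key] = np.array(
                    flat[i * cards[child] : (i + 1) * cards[child]]
                )
        cpts[child] = ConditionalProbabilityTable(child, parents, table)

    missing = [v.name for v in variables if v.name not in cpts]
    if missing:
        raise BifFormatError(f"no probability clause for {missing}")
    return BayesianNetwork(variables, cpts)


def write_bif(bn: BayesianNetwork, path) -> None:
    """Write ``bn`` so that :func:`read_bif` recovers an equal network."""
    lines = ["network unknown {", "}"]
    for var in bn.variables:
        cats = ", ".join(var.categories)
        lines += [
            f"variable {var.name} {{",
            f"  type discrete [ {var.cardinality} ] {{ {cats} }};",
            "}",
        ]
    for var in bn.variables:
        cpt = bn.cpts[var.name]
        if not cpt.parents:
            vec = ", ".join(repr(float(x)) for x in cpt.table[()])
            lines += [
                f"probability ( {var.name} ) {{",
                f"  table {vec};",
                "}",
            ]
        else:
            head = ", ".join(cpt.parents)
            lines.append(f"probability ( {var.name} | {head} ) {{")
            for key in itertools.product(
                *(range(bn.variable(p).cardinality) for p in cpt.parents)
            ):
                labels = ", ".join(
                    bn.variable(p).categories[i]
                    for p, i in zip(cpt.parents, key)
                )
                vec = ", ".join(repr(float(x)) for x in cpt.table[key])
                lines.append(f"  ( {labels} ) {vec};")
            lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Sampling and statistics
# ---------------------------------------------------------------------------


def forward_sample(bn: BayesianNetwork, n: int, seed: int) -> DiscreteDataset:
    """Ancestral sampling in topological order; deterministic per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    order = bn.topological_order()
    col_of = {name: j for j, name in enumerate(bn.names)}
    out = np.empty((n, len(bn.names)), dtype=np.int64)
    for name in order:
        cpt = bn.cpts[name]
        card = bn.variable(name).cardinality
        if cpt.parents:
            pcards = [bn.variable(p).cardinality for p in cpt.parents]
            keys = list(itertools.product(*(range(c) for c in pcards)))
            prob = np.stack([cpt.table[k] for k in keys])  # (configs, card)
            cfg = np.ravel_multi_index(
                tuple(out[:, col_of[p]] for p in cpt.parents), pcards
            )
        else:
            prob = np.asarray(cpt.table[()])[None, :]
            cfg = np.zeros(n, dtype=np.int64)
        cum = np.cumsum(prob, axis=1)
        cum[:, -1] = 1.0  # guard rounding
        u = rng.random(n)
        out[:, col_of[name]] = (u[:, None] >= cum[cfg]).sum(axis=1)
    return DiscreteDataset(list(bn.variables), out)


def exact_joint(bn: BayesianNetwork) -> np.ndarray:
    """Full joint probability table by enumeration (small networks only)."""
    cards = [v.cardinality for v in bn.variables]
    col_of = {name: j for j, name in enumerate(bn.names)}
    joint = np.zeros(cards)
    for assign in itertools.product(*(range(c) for c in cards)):
        p = 1.0
        for name in bn.names:
            cpt = bn.cpts[name]
            key = tuple(assign[col_of[q]] for q in cpt.parents)
            p *= cpt.table[key][assign[col_of[name]]]
        joint[assign] = p
    return joint


def exact_conditional_mi(
    bn: BayesianNetwork, x: str, y: str, cond: tuple[str, ...] = ()
) -> float:
    """Population conditional mutual information I(X;Y|cond) in bits,
    computed from the enumerated joint (small networks only)."""
    joint = exact_joint(bn)
    col_of = {name: j for j, name in enumerate(bn.names)}
    keep = [col_of[x], col_of[y]] + [col_of[c] for c in cond]
    drop = tuple(j for j in range(len(bn.names)) if j not in keep)
    marg = joint.sum(axis=drop) if drop else joint
    # re-order axes to (x, y, cond...)
    perm = np.argsort(np.argsort(keep))
    marg = np.transpose(marg, axes=perm)
    shape = marg.shape
    table = marg.reshape(shape[0], shape[1], -1)
    info = 0.0
    for a in range(table.shape[2]):
        sl = table[:, :, a]
        tot = sl.sum()
        if tot <= 0:
            continue
        p = sl / tot
        px = p.sum(axis=1)
        py = p.sum(axis=0)
        mask = p > 0
        info += float(
            np.sum(sl[mask] * np.log2(p[mask] / np.outer(px, py)[mask]))
        )
    return max(info, 0.0)


def identifiable_random_network(
    n_nodes: int,
    max_parents: int,
    cardinalities: tuple[int, int],
    concentration: float = 0.5,
    seed: int = 0,
    min_cmi: float = 0.01,
    min_marginal: float = 0.05,
    max_tries: int = 200,
) -> BayesianNetwork:
    """Random network screened for identifiability (small networks only).

    Draws :func:`random_network` candidates (advancing the seed) and keeps
    the first whose every adjacent pair retains at least ``min_cmi`` bits of
    exact conditional mutual information under every conditioning subset of
    the remaining nodes, and whose every marginal category probability is at
    least ``min_marginal``.  Such networks have skeletons that conditional-
    independence tests can recover at large samples; unscreened Dirichlet
    draws often contain effectively vacuous edges or near-constant nodes.
    """
    for t in range(max_tries):
        bn = random_network(
            n_nodes, max_parents, cardinalities, concentration, seed + t
        )
        joint = exact_joint(bn)
        ok = True
        for j, name in enumerate(bn.names):
            axes = tuple(k for k in range(n_nodes) if k != j)
            if joint.sum(axis=axes).min() < min_marginal:
                ok = False
                break
        if not ok:
            continue
        for a, b in bn.edges:
            others = [n for n in bn.names if n not in (a, b)]
            for r in range(len(others) + 1):
                for sub in itertools.combinations(others, r):
                    if exact_conditional_mi(bn, a, b, sub) < min_cmi:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            return bn
    raise RuntimeError("no identifiable network found within max_tries")


def network_stats(bn: BayesianNetwork) -> NetworkStats:
    names = bn.names
    n_nodes = len(names)
    edges = bn.edges
    n_edges = len(edges)
    n_parameters = 0
    for name in names:
        cpt = bn.cpts[name]
        block = bn.variable(name).cardinality - 1
        for p in cpt.parents:
            block *= bn.variable(p).cardinality
        n_parameters += block
    mb_sizes = []
    for name in names:
        blanket: set[str] = set(bn.parents(name))
        for child in bn.children(name):
            blanket.add(child)
            blanket.update(bn.parents(child))
        blanket.discard(name)
        mb_sizes.append(len(blanket))
    max_in = max(len(bn.parents(n)) for n in names)
    return NetworkStats(
        n_nodes=n_nodes,
        n_edges=n_edges,
        n_parameters=n_parameters,
        avg_degree=2.0 * n_edges / n_nodes,
        avg_markov_blanket=float(np.mean(mb_sizes)),
        max_in_degree=max_in,
    )


def random_network(
    n_nodes: int,
    max_parents: int,
    cardinalities: tuple[int, int],
    concentration: float,
    seed: int,
) -> BayesianNetwork:
    """Seeded random network: acyclic by construction (parents drawn only
    from earlier nodes in a random permutation), CPT rows from a symmetric
    Dirichlet with the given concentration.  Small concentrations give
    near-deterministic rows, hence strong dependences."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if max_parents >= n_nodes:
        raise ValueError("max_parents must be < n_nodes")
    lo, hi = cardinalities
    if lo < 2 or hi < lo:
        raise ValueError("cardinality range must satisfy 2 <= lo <= hi")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_nodes)))
    names = [f"X{str(i + 1).zfill(width)}" for i in range(n_nodes)]
    cards = {n: int(rng.integers(lo, hi + 1)) for n in names}
    order = [names[i] for i in rng.permutation(n_nodes)]
    variables = [
        CategoricalVariable(n, tuple(f"c{k}" for k in range(cards[n])))
        for n in names
    ]
    cpts: dict[str, ConditionalProbabilityTable] = {}
    for pos, name in enumerate(order):
        avail = order[:pos]
        k = int(rng.integers(0, min(max_parents, len(avail)) + 1))
        parents = tuple(
            sorted(rng.choice(avail, size=k, replace=False).tolist())
        ) if k else ()
        keys = list(
            itertools.product(*(range(cards[p]) for p in parents))
        )
        alpha = np.full(cards[name], concentration)
        table = {key: rng.dirichlet(alpha) for key in keys}
        cpts[name] = ConditionalProbabilityTable(name, parents, table)
    return BayesianNetwork(variables, cpts)


def demo_network() -> BayesianNetwork:
    """Built-in 8-node benchmark fixture with strong, hand-specified CPTs.

    Nine edges covering a chain, a fork and three colliders; every CPT row
    is bounded away from determinism so all marginals are non-degenerate at
    realistic sample sizes, while the parent effects stay large enough for
    skeleton recovery experiments.
    """
    b2 = ("c0", "c1")
    b3 = ("c0", "c1", "c2")
    variables = [
        CategoricalVariable("X1", b2),
        CategoricalVariable("X2", b3),
        CategoricalVariable("X3", b2),
        CategoricalVariable("X4", b3),
        CategoricalVariable("X5", b2),
        CategoricalVariable("X6", b2),
        CategoricalVariable("X7", b3),
        CategoricalVariable("X8", b2),
    ]

    def binary(p0: dict[tuple[int, ...], float], parents: tuple[str, ...], child: str):
        return ConditionalProbabilityTable(
            child, parents,
            {k: np.array([p, 1.0 - p]) for k, p in p0.items()},
        )

    cpts = {
        "X1": ConditionalProbabilityTable("X1", (), {(): np.array([0.4, 0.6])}),
        "X2": ConditionalProbabilityTable(
            "X2", (), {(): np.array([0.3, 0.45, 0.25])}
        ),
        "X3": binary(
            {(0, 0): 0.9, (0, 1): 0.7, (0, 2): 0.2,
             (1, 0): 0.6, (1, 1): 0.15, (1, 2): 0.8},
            ("X1", "X2"), "X3",
        ),
        "X4": ConditionalProbabilityTable(
            "X4", ("X2",),
            {(0,): np.array([0.7, 0.2, 0.1]),
             (1,): np.array([0.15, 0.7, 0.15]),
             (2,): np.array([0.1, 0.25, 0.65])},
        ),
        "X5": binary({(0,): 0.85, (1,): 0.25}, ("X3",), "X5"),
        "X6": binary(
            {(0, 0): 0.9, (0, 1): 0.55, (0, 2): 0.2,
             (1, 0): 0.7, (1, 1): 0.3, (1, 2): 0.1},
            ("X3", "X4"), "X6",
        ),
        "X7": ConditionalProbabilityTable(
            "X7", ("X5",),
            {(0,): np.array([0.6, 0.3, 0.1]),
             (1,): np.array([0.1, 0.3, 0.6])},
        ),
        "X8": binary(
            {(0, 0): 0.95, (0, 1): 0.5, (0, 2): 0.1,
             (1, 0): 0.7, (1, 1): 0.25, (1, 2): 0.85},
            ("X6", "X7"), "X8",
        ),
    }
    return BayesianNetwork(variables, cpts)
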