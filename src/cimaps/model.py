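"""Model/Results facade over the structure-learning pipeline.

``CIMapModel`` is built from data and configuration; ``fit()`` runs the PC
search and returns ``CIMapResults`` carrying the learned CI-map, diagnostics
and a ``summary()`` table.  ``CIMapResults.to_dag()`` orients the map and
returns ``DagResults`` with the BIC score.  ``BootstrapCIMapModel`` wraps the
bootstrap stability-selection procedure around a target variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .bn import DiscreteDataset
from .bootstrap import (
    AssociationHistogram,
    FilterConfig,
    association_histogram,
    bootstrap_cimaps,
    hierarchical_filter,
)
from .independence import FnrConfig
from .orientation import ScoredDag, cimap_to_dag
from .skeleton import CIMap, FdrPolicy, learn_skeleton

__all__ = [
    "CIMapModel",
    "CIMapResults",
    "DagResults",
    "BootstrapCIMapModel",
    "BootstrapResults",
]


@dataclass
class CIMapModel:
    """Constraint-based structure model for a discrete dataset."""

    data: DiscreteDataset
    alpha: float = 0.05
    fdr: str | FdrPolicy | None = "basic"
    fnr: FnrConfig | None = None

    @classmethod
    def from_dataframe(cls, df, **kwargs) -> "CIMapModel":
        return cls(DiscreteDataset.from_dataframe(df), **kwargs)

    def fit(self) -> "CIMapResults":
        cimap = learn_skeleton(
            self.data, alpha=self.alpha, fdr=self.fdr, fnr=self.fnr
        )
        return CIMapResults(model=self, cimap=cimap)


@dataclass
class CIMapResults:
    model: CIMapModel
    cimap: CIMap

    @property
    def edges(self) -> set:
        return self.cimap.edges

    def summary(self) -> str:
        log = self.cimap.policy_log
        lines = [
            "Conditional-independence map",
            "=" * 34,
            f"nodes:            {len(self.cimap.nodes)}",
            f"edges:            {len(self.cimap.edges)}",
            f"alpha:            {self.cimap.alpha}",
            f"FDR policy:       {log.get('fdr')}",
            f"FNR gate:         {log.get('fnr') or 'disabled'}",
            f"tests performed:  {log.get('tests_performed')}",
            f"tests skipped:    {log.get('tests_skipped')}",
            "",
            "edge                             MI (bits)",
            "-" * 43,
        ]
        for e in sorted(self.cimap.edges, key=lambda s: tuple(sorted(s))):
            a, b = sorted(e)
            lines.append(f"{a:>12s} -- {b:<12s}   {self.cimap.mi_weight[e]:.4f}")
        return "\n".join(lines)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"a": a, "b": b, "mi_bits": self.cimap.mi_weight[e]}
            for e in sorted(self.cimap.edges, key=lambda s: tuple(sorted(s)))
            for a, b in [sorted(e)]
        ]
        return pd.DataFrame(rows, columns=["a", "b", "mi_bits"])

    def to_dag(self, max_iter: int = 100, seed: int = 0) -> "DagResults":
        scored = cimap_to_dag(
            self.cimap, self.model.data, max_iter=max_iter, seed=seed
        )
        return DagResults(results=self, scored=scored)


@dataclass
class DagResults:
    results: CIMapResults
    scored: ScoredDag

    @property
    def bic(self) -> float:
        return self.scored.bic

    @property
    def dag(self):
        return self.scored.dag

    def summary(self) -> str:
        lines = [
            "BIC-scored Bayesian network",
            "=" * 34,
            f"nodes:       {self.scored.dag.number_of_nodes()}",
            f"edges:       {self.scored.dag.number_of_edges()}",
            f"BIC score:   {self.scored.bic:.4f}",
            f"order policy:{self.scored.policy:>8s}",
            "",
            "directed edges",
            "-" * 34,
        ]
        for a, b in sorted(self.scored.dag.edges):
            lines.append(f"{a:>12s} -> {b}")
        return "\n".join(lines)


@dataclass
class BootstrapCIMapModel:
    """Bootstrap stability selection of the CI-map around a target node."""

    data: DiscreteDataset
    target: str
    alpha: float = 0.05
    fdr: str | FdrPolicy | None = "basic"
    fnr: FnrConfig | None = None
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)

    def __post_init__(self) -> None:
        if self.target not in self.data.names:
            raise KeyError(f"target {self.target!r} is not a column")

    def fit(self, b: int = 400, seed: int = 0) -> "BootstrapResults":
        maps = bootstrap_cimaps(
            self.data, b=b, alpha=self.alpha, fdr=self.fdr,
            fnr=self.fnr, seed=seed,
        )
        hist = association_histogram(maps, self.target)
        chosen = hierarchical_filter(maps, self.target, self.filter_cfg)
        return BootstrapResults(
            model=self, maps=maps, histogram=hist, representative=chosen
        )


@dataclass
class BootstrapResults:
    model: BootstrapCIMapModel
    maps: list[CIMap]
    histogram: AssociationHistogram
    representative: CIMap

    def summary(self) -> str:
        h = self.histogram
        lines = [
            "Bootstrapped CI-map selection",
            "=" * 34,
            f"target:         {h.target}",
            f"bootstrap maps: {h.n_maps}",
            f"representative map edges: {len(self.representative.edges)}",
            "",
            "node          1st-order %   2nd-order %",
            "-" * 41,
        ]
        for n in sorted(
            h.first_order, key=lambda n: (-h.first_order[n], n)
        ):
            lines.append(
                f"{n:>10s}    {h.first_order[n]:>8.1f}    {h.second_order[n]:>8.1f}"
            )
        return "\n".join(lines)
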