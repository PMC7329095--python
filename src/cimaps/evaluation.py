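"""Structure-error metrics and experiment drivers.

Learned structures are scored against the generating network by counting
excess edges (false positives), missing edges (false negatives) and, for
DAGs, common edges oriented the wrong way round.  The drivers reproduce the
benchmark protocols: paired comparison of the FDR policies, the effect-size
scan that locates the w minimising total skeleton errors, the sample-size
scan, and the node-order experiment comparing strongest-first / weakest-first
/ best-of-k-random BIC scores.

Replicate seeds are derived from the master seed with spawn keys, so adding
replicates never perturbs earlier ones, and all policies see identical
datasets (paired design).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .bn import BayesianNetwork, DiscreteDataset, forward_sample
from .independence import FnrConfig
from .orientation import OrderPolicy, bic_score, cimap_to_dag, extend_to_dag, orient_v_structures, rule_closure
from .skeleton import CIMap, FdrPolicy, learn_skeleton

__all__ = [
    "SkeletonErrors",
    "DagErrors",
    "ScanResult",
    "skeleton_errors",
    "dag_errors",
    "fdr_comparison",
    "effect_size_scan",
    "sample_size_scan",
    "node_order_experiment",
]


@dataclass(frozen=True)
class SkeletonErrors:
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.fp + self.fn


@dataclass(frozen=True)
class DagErrors:
    skeleton: SkeletonErrors
    direction: int


@dataclass
class ScanResult:
    grid: list[float]
    mean_fp: list[float]
    mean_fn: list[float]
    mean_total: list[float]
    sd_total: list[float]
    argmin: float
    extras: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "grid": self.grid,
                "mean_fp": self.mean_fp,
                "mean_fn": self.mean_fn,
                "mean_total": self.mean_total,
                "sd_total": self.sd_total,
            }
        )


def _replicate_seed(master: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(master, spawn_key=tuple(key))


def _seed_int(master: int, *key: int) -> int:
    return int(_replicate_seed(master, *key).generate_state(1)[0] % (2**31))


def skeleton_errors(learned: CIMap, truth: BayesianNetwork) -> SkeletonErrors:
    if set(learned.nodes) != set(truth.names):
        raise ValueError("node sets differ")
    true_skel = truth.skeleton()
    fp = len(learned.edges - true_skel)
    fn = len(true_skel - learned.edges)
    return SkeletonErrors(fp=fp, fn=fn)


def dag_errors(learned: nx.DiGraph, truth: BayesianNetwork) -> DagErrors:
    if set(learned.nodes) != set(truth.names):
        raise ValueError("node sets differ")
    learned_dir = set(learned.edges)
    learned_skel = {frozenset(e) for e in learned_dir}
    true_dir = truth.edges
    true_skel = truth.skeleton()
    fp = len(learned_skel - true_skel)
    fn = len(true_skel - learned_skel)
    direction = sum(
        1
        for a, b in true_dir
        if frozenset((a, b)) in learned_skel and (b, a) in learned_dir
    )
    return DagErrors(SkeletonErrors(fp=fp, fn=fn), direction)


def fdr_comparison(
    bn: BayesianNetwork,
    n: int,
    reps: int,
    policies: tuple[str, ...] = ("basic", "interleaved", "mini"),
    alpha: float = 0.05,
    fnr: FnrConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean +- sd of FN / FP / total skeleton errors per FDR policy over
    ``reps`` shared datasets (paired design)."""
    if reps < 2:
        raise ValueError("reps must be >= 2 for a standard deviation")
    datasets = [
        forward_sample(bn, n, _seed_int(seed, r)) for r in range(reps)
    ]
    rows = []
    for policy in policies:
        errs = [
            skeleton_errors(
                learn_skeleton(d, alpha=alpha, fdr=policy, fnr=fnr), bn
            )
            for d in datasets
        ]
        fn = np.array([e.fn for e in errs], dtype=float)
        fp = np.array([e.fp for e in errs], dtype=float)
        tot = fn + fp
        rows.append(
            {
                "policy": policy,
                "fn_mean": fn.mean(), "fn_sd": fn.std(ddof=1),
                "fp_mean": fp.mean(), "fp_sd": fp.std(ddof=1),
                "total_mean": tot.mean(), "total_sd": tot.std(ddof=1),
            }
        )
    return pd.DataFrame(rows)


def effect_size_scan(
    bn: BayesianNetwork,
    n: int,
    w_grid: list[float],
    reps: int = 10,
    alpha: float = 0.05,
    beta: float = 0.05,
    fdr: str | None = "basic",
    seed: int = 0,
) -> ScanResult:
    """Skeleton errors as a function of the FNR effect size w, on shared
    datasets, plus an FNR-disabled reference line in ``extras``."""
    if not w_grid:
        raise ValueError("empty effect-size grid")
    datasets = [
        forward_sample(bn, n, _seed_int(seed, r)) for r in range(reps)
    ]
    mean_fp, mean_fn, mean_total, sd_total = [], [], [], []
    for w in w_grid:
        fnr = FnrConfig(enabled=True, alpha=alpha, beta=beta, effect_size=w)
        errs = [
            skeleton_errors(
                learn_skeleton(d, alpha=alpha, fdr=fdr, fnr=fnr), bn
            )
            for d in datasets
        ]
        fp = np.array([e.fp for e in errs], dtype=float)
        fn = np.array([e.fn for e in errs], dtype=float)
        tot = fp + fn
        mean_fp.append(fp.mean())
        mean_fn.append(fn.mean())
        mean_total.append(tot.mean())
        sd_total.append(tot.std(ddof=1) if reps > 1 else 0.0)
    ref = [
        skeleton_errors(
            learn_skeleton(d, alpha=alpha, fdr=fdr, fnr=None), bn
        ).total
        for d in datasets
    ]
    # ties broken toward the larger w (fewer skipped tests)
    best = max(
        range(len(w_grid)),
        key=lambda i: (-mean_total[i], w_grid[i]),
    )
    return ScanResult(
        grid=list(w_grid),
        mean_fp=mean_fp,
        mean_fn=mean_fn,
        mean_total=mean_total,
        sd_total=sd_total,
        argmin=w_grid[best],
        extras={"fnr_disabled_mean_total": float(np.mean(ref))},
    )


def sample_size_scan(
    bn: BayesianNetwork,
    sizes: list[int],
    reps: int = 10,
    alpha: float = 0.05,
    fdr: str | None = "basic",
    fnr: FnrConfig | None = None,
    seed: int = 0,
) -> ScanResult:
    """Skeleton errors per sample size, plus DAG errors averaged from one
    random-order DAG per CI-map (in ``extras``)."""
    if not sizes:
        raise ValueError("empty size grid")
    mean_fp, mean_fn, mean_total, sd_total = [], [], [], []
    dag_totals = []
    for si, n in enumerate(sizes):
        fps, fns, dag_tot = [], [], []
        for r in range(reps):
            d = forward_sample(bn, n, _seed_int(seed, si, r))
            cimap = learn_skeleton(d, alpha=alpha, fdr=fdr, fnr=fnr)
            e = skeleton_errors(cimap, bn)
            fps.append(e.fp)
            fns.append(e.fn)
            pdag = rule_closure(orient_v_structures(cimap))
            dag = extend_to_dag(
                pdag,
                OrderPolicy("random", seed=_seed_int(seed, si, r, 1)),
                cimap.mi_weight,
            )
            de = dag_errors(dag, bn)
            dag_tot.append(de.skeleton.total + de.direction)
        fp = np.array(fps, dtype=float)
        fn = np.array(fns, dtype=float)
        tot = fp + fn
        mean_fp.append(fp.mean())
        mean_fn.append(fn.mean())
        mean_total.append(tot.mean())
        sd_total.append(tot.std(ddof=1) if reps > 1 else 0.0)
        dag_totals.append(float(np.mean(dag_tot)))
    best = int(np.argmin(mean_total))
    return ScanResult(
        grid=[float(s) for s in sizes],
        mean_fp=mean_fp,
        mean_fn=mean_fn,
        mean_total=mean_total,
        sd_total=sd_total,
        argmin=float(sizes[best]),
        extras={"dag_mean_total": dag_totals},
    )


def node_order_experiment(
    bn: BayesianNetwork,
    n_datasets: int = 100,
    n_obs: int = 25_000,
    random_set_sizes: tuple[int, ...] = (1, 25, 100),
    alpha: float = 0.05,
    fdr: str | None = "basic",
    seed: int = 0,
) -> pd.DataFrame:
    """Per dataset: TSF and TWF BIC scores plus best/worst of k random
    orders for each k; one row per dataset."""
    k_max = max(random_set_sizes)
    rows = []
    for r in range(n_datasets):
        d = forward_sample(bn, n_obs, _seed_int(seed, r))
        cimap = learn_skeleton(d, alpha=alpha, fdr=fdr)
        pdag = rule_closure(orient_v_structures(cimap))
        row: dict[str, float] = {"dataset": r}
        for kind in ("TSF", "TWF"):
            dag = extend_to_dag(pdag, OrderPolicy(kind), cimap.mi_weight)
            row[kind.lower()] = bic_score(dag, d)
        scores = []
        for i in range(k_max):
            dag = extend_to_dag(
                pdag,
                OrderPolicy("random", seed=_seed_int(seed, r, i)),
                cimap.mi_weight,
            )
            scores.append(bic_score(dag, d))
        for k in random_set_sizes:
            row[f"best_of_{k}"] = max(scores[:k])
            row[f"worst_of_{k}"] = min(scores[:k])
        rows.append(row)
    return pd.DataFrame(rows)
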