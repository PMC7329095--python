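"""Conditional-independence machinery for categorical data.

The dependence statistic is the G-test

    G = 2 * sum_{i,j,A} O_{ij|A} * ln(O_{ij|A} / E_{ij|A})

with expected counts computed under independence within each conditioning
slice A, degrees of freedom df = (|i|-1)(|j|-1)*|A|, and the asymptotic
chi-square reference distribution.  The plug-in mutual information (base-2
logarithm) satisfies the identity G = 2 N ln(2) I, which ties the
information-theoretic edge weights of a CI-map to the test statistic.

Two gates can stop a test from being performed, in which case the default
decision is to keep the edge:

* the false-negative-reduction (FNR) gate skips any test whose chi-square
  power against the noncentrality N*w^2 (Cohen's effect size w) would fall
  below 1 - beta;
* the reliability gate skips any test with fewer than five observations per
  degree of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import special, stats

from .bn import DiscreteDataset

__all__ = [
    "ContingencyTable",
    "CITestResult",
    "FnrConfig",
    "contingency",
    "g_statistic",
    "mutual_information",
    "fnr_max_dof",
    "ci_test",
    "MIN_OBS_PER_DOF",
]

#: reliability rule of thumb: the G statistic is not trusted as a chi-square
#: approximation below five observations per degree of freedom.
MIN_OBS_PER_DOF = 5.0

INDEPENDENT = "independent"
DEPENDENT = "dependent"
UNTESTED_KEEP_EDGE = "untested-keep-edge"


@dataclass
class ContingencyTable:
    """Observed counts O_{ij|A} for a variable pair under a conditioning set.

    ``counts`` has shape ``(x_card, y_card, n_configs)`` where ``n_configs``
    is the product of the conditioning cardinalities (1 when unconditioned).
    """

    x_card: int
    y_card: int
    cond_cards: tuple[int, ...]
    counts: np.ndarray
    n_total: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        n_cfg = int(np.prod(self.cond_cards)) if self.cond_cards else 1
        if self.counts.shape != (self.x_card, self.y_card, n_cfg):
            raise ValueError("counts shape does not match cardinalities")
        if (self.counts < 0).any():
            raise ValueError("negative count")
        if abs(self.counts.sum() - self.n_total) > 1e-6:
            raise ValueError("counts do not sum to n_total")

    @property
    def dof(self) -> int:
        n_cfg = int(np.prod(self.cond_cards)) if self.cond_cards else 1
        return (self.x_card - 1) * (self.y_card - 1) * n_cfg


@dataclass(frozen=True)
class FnrConfig:
    """Parameters of the false-negative-reduction gate."""

    enabled: bool = True
    alpha: float = 0.05
    beta: float = 0.05
    effect_size: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.beta < 1:
            raise ValueError("beta must lie in (0, 1)")
        if self.enabled and self.effect_size <= 0:
            raise ValueError("effect_size must be positive when enabled")


@dataclass(frozen=True)
class CITestResult:
    g_stat: float
    mi_bits: float
    dof: int
    p_value: float
    performed: bool
    alpha_used: float
    verdict: str

    @property
    def independent(self) -> bool:
        return self.verdict == INDEPENDENT


def contingency(
    data: DiscreteDataset,
    x: str,
    y: str,
    cond: tuple[str, ...] | list[str] | frozenset = (),
) -> ContingencyTable:
    """Exact co-occurrence tallies of (x, y) within every conditioning cell."""
    cond = tuple(sorted(cond))
    if x == y:
        raise ValueError("x and y must differ")
    if x in cond or y in cond:
        raise ValueError("conditioning set must exclude x and y")
    xc = data.column(x)
    yc = data.column(y)
    x_card = data.cardinality(x)
    y_card = data.cardinality(y)
    cond_cards = tuple(data.cardinality(c) for c in cond)
    n_cfg = int(np.prod(cond_cards)) if cond else 1
    if cond:
        cfg = np.ravel_multi_index(
            tuple(data.column(c) for c in cond), cond_cards
        )
    else:
        cfg = np.zeros(data.n, dtype=np.int64)
    flat = (xc * y_card + yc) * n_cfg + cfg
    counts = np.bincount(flat, minlength=x_card * y_card * n_cfg).reshape(
        x_card, y_card, n_cfg
    )
    return ContingencyTable(x_card, y_card, cond_cards, counts, data.n)


def g_statistic(table: ContingencyTable) -> tuple[float, int]:
    """G = 2 sum O ln(O/E) with slice-wise expected counts; empty slices
    contribute 0 and do not reduce the (unconditional) df formula."""
    if table.n_total < 1:
        raise ValueError("empty table")
    O = table.counts
    tot = O.sum(axis=(0, 1))  # per-slice totals
    g = 0.0
    for a in np.nonzero(tot > 0)[0]:
        sl = O[:, :, a]
        rows = sl.sum(axis=1)
        cols = sl.sum(axis=0)
        E = np.outer(rows, cols) / tot[a]
        mask = sl > 0
        g += 2.0 * float(np.sum(sl[mask] * np.log(sl[mask] / E[mask])))
    return max(g, 0.0), table.dof


def mutual_information(table: ContingencyTable) -> float:
    """Plug-in conditional mutual information in bits.

    I = sum_{i,j,A} P(i,j,A) log2( P(i,j|A) / (P(i|A) P(j|A)) ), with all
    probabilities taken as empirical frequencies.
    """
    if table.n_total < 1:
        raise ValueError("empty table")
    O = table.counts
    N = float(table.n_total)
    tot = O.sum(axis=(0, 1))
    info = 0.0
    for a in np.nonzero(tot > 0)[0]:
        sl = O[:, :, a]
        p_joint = sl / tot[a]
        p_x = p_joint.sum(axis=1)
        p_y = p_joint.sum(axis=0)
        mask = sl > 0
        ratio = p_joint[mask] / np.outer(p_x, p_y)[mask]
        info += float(np.sum((sl[mask] / N) * np.log2(ratio)))
    return max(info, 0.0)


@lru_cache(maxsize=4096)
def _fnr_max_dof_cached(
    n: int, alpha: float, beta: float, w: float
) -> int:
    lam = n * w * w

    def power(df: int) -> float:
        crit = stats.chi2.isf(alpha, df)
        return float(stats.ncx2.sf(crit, df, lam))

    target = 1.0 - beta
    if power(1) < target:
        return 0
    lo, hi = 1, 2
    cap = 10**8
    while power(hi) >= target:
        lo = hi
        hi *= 4
        if hi > cap:
            return cap
    # power is decreasing in df at fixed noncentrality
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power(mid) >= target:
            lo = mid
        else:
            hi = mid
    return lo


def fnr_max_dof(n: int, cfg: FnrConfig) -> int:
    """Largest df at which a level-alpha chi-square test retains power
    >= 1 - beta against noncentrality n * w^2 (0 means every test is
    skipped and the graph stays fully connected)."""
    if not cfg.enabled:
        raise ValueError("FNR gate is disabled")
    if n < 1:
        raise ValueError("n must be >= 1")
    return _fnr_max_dof_cached(
        int(n), float(cfg.alpha), float(cfg.beta), float(cfg.effect_size)
    )


def ci_test(
    data: DiscreteDataset,
    x: str,
    y: str,
    cond: tuple[str, ...] | list[str] | frozenset = (),
    alpha: float = 0.05,
    fnr: FnrConfig | None = None,
) -> CITestResult:
    """One conditional-independence G-test with the FNR and reliability gates.

    A gated (skipped) test returns ``performed=False`` and the PC default
    verdict ``untested-keep-edge``.
    """
    table = contingency(data, x, y, cond)
    df = table.dof
    n = table.n_total
    if fnr is not None and fnr.enabled and df > fnr_max_dof(n, fnr):
        return CITestResult(
            g_stat=0.0, mi_bits=0.0, dof=df, p_value=math.nan,
            performed=False, alpha_used=alpha, verdict=UNTESTED_KEEP_EDGE,
        )
    if n / df < MIN_OBS_PER_DOF:
        return CITestResult(
            g_stat=0.0, mi_bits=0.0, dof=df, p_value=math.nan,
            performed=False, alpha_used=alpha, verdict=UNTESTED_KEEP_EDGE,
        )
    g, _ = g_statistic(table)
    mi = mutual_information(table)
    p = float(special.chdtrc(df, g))
    verdict = INDEPENDENT if p >= alpha else DEPENDENT
    return CITestResult(
        g_stat=g, mi_bits=mi, dof=df, p_value=p,
        performed=True, alpha_used=alpha, verdict=verdict,
    )
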