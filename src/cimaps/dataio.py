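"""Dataset I/O, quantile discretisation and the synthetic spectroscopy-like
fixture generator.

Continuous feature tables (emulating per-subject metabolite peak intensities
from single-voxel 1H-MRS, with a binary tissue-class label) are discretised
into equal-frequency bins before CI-map learning.  The number of categories
is budgeted so that the worst-case pairwise test keeps at least five
observations per degree of freedom, i.e. the largest c with
n / (c-1)^2 >= 5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bn import CategoricalVariable, DiscreteDataset

__all__ = [
    "ContinuousTable",
    "METABOLITE_NAMES",
    "read_table",
    "discretize_quantiles",
    "category_budget",
    "synth_mrs_table",
]

#: the clinically relevant 1H-MRS signals modelled by the fixture generator
METABOLITE_NAMES = (
    "ML", "Lac", "Ala1", "Ala2", "NAA",
    "PCr", "Cho", "Tau", "GlyMIns", "Glx",
)


@dataclass
class ContinuousTable:
    """Real-valued feature table with an optional binary target column."""

    features: pd.DataFrame
    target: pd.Series | None = None
    target_name: str = "class"

    def __post_init__(self) -> None:
        if self.features.isna().any().any():
            rows = self.features.index[
                self.features.isna().any(axis=1)
            ].tolist()
            raise ValueError(f"missing feature values in rows {rows}")
        if self.target is not None:
            if self.target.isna().any():
                raise ValueError("missing values in target column")
            if self.target.nunique() != 2:
                raise ValueError("target must have exactly 2 levels")

    @property
    def n(self) -> int:
        return len(self.features)

    def to_dataframe(self) -> pd.DataFrame:
        df = self.features.copy()
        if self.target is not None:
            df[self.target_name] = self.target.values
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def read_table(
    path,
    categorical: bool | list[str] | None = None,
    target: str | None = None,
):
    """Read a CSV with a header row.

    ``categorical=True`` (or a column list covering every column) yields a
    :class:`DiscreteDataset` with category labels preserved verbatim;
    otherwise a :class:`ContinuousTable`, with ``target`` split off as the
    binary class column when named.
    """
    # pandas silently renames duplicate headers, so check the raw header row
    header = (
        pd.read_csv(path, header=None, nrows=1).iloc[0].astype(str).tolist()
    )
    dupes = sorted({h for h in header if header.count(h) > 1})
    if dupes:
        raise ValueError(f"duplicate column headers: {dupes}")
    df = pd.read_csv(path, dtype=str if categorical is True else None)
    if df.isna().any().any():
        bad = [
            (int(i), str(c))
            for i, c in zip(*np.where(df.isna().to_numpy()))
        ]
        raise ValueError(
            "empty cells at (row, column index) " + repr(bad[:20])
        )
    if categorical is True:
        return DiscreteDataset.from_dataframe(df)
    tgt = None
    if target is not None:
        tgt = df[target].astype(str)
        df = df.drop(columns=[target])
    feats = df.astype(float)
    return ContinuousTable(feats, tgt, target or "class")


def category_budget(
    n: int, cond_depth: int = 0, max_categories: int = 20
) -> int:
    """Largest category count c >= 2 keeping five observations per degree of
    freedom in the worst-case pairwise test.

    With ``cond_depth`` conditioning variables of the same cardinality the
    binding df is (c-1)^2 * c^cond_depth; the default 0 uses the
    unconditional pairwise test as a pre-flight guard (the same rule is also
    applied per test at run time).  Returns 1 with a warning when even c = 2
    is infeasible.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    best = 1
    for c in range(2, max_categories + 1):
        df = (c - 1) ** 2 * c**cond_depth
        if n / df >= 5:
            best = c
        else:
            break
    if best == 1:
        warnings.warn(
            "sample too small for even two categories per variable",
            stacklevel=2,
        )
    return best


def discretize_quantiles(
    table: ContinuousTable, n_categories: int = 3
) -> DiscreteDataset:
    """Equal-frequency binning at the k/n_categories empirical quantiles.

    Values tied with a cut point fall into the lower bin; the target column
    passes through untouched as a categorical variable.
    """
    if n_categories < 2:
        raise ValueError("n_categories must be >= 2")
    variables: list[CategoricalVariable] = []
    cols: list[np.ndarray] = []
    labels = tuple(f"q{k + 1}" for k in range(n_categories))
    probs = [k / n_categories for k in range(1, n_categories)]
    for name in table.features.columns:
        x = table.features[name].to_numpy(dtype=float)
        if len(np.unique(x)) < n_categories:
            raise ValueError(
                f"feature {name!r} has fewer than {n_categories} distinct "
                "values"
            )
        cuts = np.quantile(x, probs)
        codes = np.searchsorted(cuts, x, side="left")
        variables.append(CategoricalVariable(str(name), labels))
        cols.append(codes)
    if table.target is not None:
        levels = tuple(sorted(table.target.astype(str).unique()))
        lookup = {lv: i for i, lv in enumerate(levels)}
        variables.append(
            CategoricalVariable(table.target_name, levels)
        )
        cols.append(
            table.target.astype(str).map(lookup).to_numpy()
        )
    return DiscreteDataset(variables, np.column_stack(cols))


def synth_mrs_table(
    n_subjects: int = 239,
    n_features: int = 10,
    class_fraction: float = 0.25,
    effect: dict[str, float] | list[float] | None = None,
    latent_corr: float | np.ndarray = 0.3,
    seed: int = 0,
) -> ContinuousTable:
    """Synthetic stand-in for a single-voxel MRS metabolite cohort.

    Each subject carries ``n_features`` correlated Gaussian peak intensities
    and a binary tissue-class label; class membership shifts the feature
    means by ``effect`` (in within-class standard-deviation units).  The
    defaults mirror a 239-subject cohort with a roughly quarter-prevalence
    tumour class and a mild shared correlation between metabolites.  Feature
    names follow the usual metabolite shorthand when ``n_features <= 10``.
    """
    if n_features < 2:
        raise ValueError("need at least 2 features")
    if not 0 < class_fraction < 1:
        raise ValueError("class_fraction must lie in (0, 1)")
    if n_features <= len(METABOLITE_NAMES):
        names = list(METABOLITE_NAMES[:n_features])
    else:
        names = [f"F{i + 1}" for i in range(n_features)]
    if effect is None:
        shifts = np.zeros(n_features)
    elif isinstance(effect, dict):
        unknown = set(effect) - set(names)
        if unknown:
            raise ValueError(f"effect names unknown: {sorted(unknown)}")
        shifts = np.array([effect.get(n, 0.0) for n in names])
    else:
        shifts = np.asarray(effect, dtype=float)
        if shifts.shape != (n_features,):
            raise ValueError(
                f"effect must have length {n_features}, got {shifts.shape}"
            )
    if np.isscalar(latent_corr):
        rho = float(latent_corr)
        cov = np.full((n_features, n_features), rho)
        np.fill_diagonal(cov, 1.0)
    else:
        cov = np.asarray(latent_corr, dtype=float)
        if cov.shape != (n_features, n_features):
            raise ValueError("correlation matrix has wrong shape")
    rng = np.random.default_rng(seed)
    n_pos = int(round(class_fraction * n_subjects))
    labels = np.zeros(n_subjects, dtype=int)
    labels[rng.permutation(n_subjects)[:n_pos]] = 1
    chol = np.linalg.cholesky(cov)
    noise = rng.standard_normal((n_subjects, n_features)) @ chol.T
    values = noise + labels[:, None] * shifts[None, :]
    features = pd.DataFrame(values, columns=names)
    target = pd.Series(
        np.where(labels == 1, "case", "control"), name="class"
    )
    return ContinuousTable(features, target, "class")
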