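"""Multivariate perceived-stress screening against telomere length.

Mixed-type survey features are screened one at a time against an LTL
outcome with a type-dispatched nonparametric test — Kendall's tau-b for
numeric features, Kruskal-Wallis across levels for categorical features,
and the two-sided Wilcoxon rank-sum for binary features. For the
feature-relationship view, missing cells are median-imputed (mode for
categorical), the Spearman correlation matrix of all features is
computed, and t-SNE on the rows of the absolute correlation matrix
places features in 2-D; edges join pairs with |r| >= 0.3 (thin) or
|r| >= 0.7 (thick), nodes are sized by -log10(p) and colored by
association direction when p < 0.1 (bold labels at p < 0.05). A support
vector machine evaluated by 10-fold cross-validation asks whether the
profile as a whole predicts LTL, judged against a permutation null. No
multiple-comparison adjustment is applied to the univariate screen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import TSNE
from sklearn.model_selection import KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .cohort import rank_sum_test

__all__ = [
    "StressFeatureTable",
    "AssociationResult",
    "CVPredictResult",
    "classify_feature",
    "univariate_association",
    "impute_median",
    "correlation_network",
    "network_to_json",
    "cv_predict",
    "TypingError",
]

#: Edge thresholds on absolute Spearman correlation.
THIN_EDGE_R = 0.3
THICK_EDGE_R = 0.7
#: Node-annotation p-value thresholds (color / bold).
COLOR_P = 0.1
BOLD_P = 0.05

_TEST_BY_KIND = {"numeric": "kendall-tau", "categorical": "kruskal-wallis",
                 "binary": "rank-sum"}


class TypingError(ValueError):
    """A feature's type cannot be inferred (e.g. all values missing)."""


@dataclass
class StressFeatureTable:
    """Subjects x features survey table with declared per-feature types.

    ``data`` is numeric-coded (categorical features as level codes);
    missingness is NaN. ``types`` maps feature name to
    numeric|categorical|binary.
    """

    data: pd.DataFrame
    types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        inferred = {}
        for name in self.data.columns:
            declared = self.types.get(name)
            inferred[name] = classify_feature(self.data[name], declared=declared)
        self.types = inferred

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()


@dataclass(frozen=True)
class AssociationResult:
    feature: str
    test: str
    statistic: float
    p_value: float
    direction: int
    n: int


@dataclass(frozen=True)
class CVPredictResult:
    r2: float
    mse: float
    null_r2: np.ndarray
    p_value: float
    significant: bool


def classify_feature(values: Sequence, declared: str | None = None) -> str:
    """Infer a feature's type: binary, categorical, or numeric.

    At most 2 observed levels is binary; non-numeric values or integer
    codes with at most 6 distinct levels are categorical; anything else
    is numeric. An explicit declaration wins.
    """
    if declared is not None:
        if declared not in _TEST_BY_KIND:
            raise ValueError(f"unknown feature type {declared!r}")
        return declared
    series = pd.Series(list(values)).dropna()
    if series.empty:
        raise TypingError("cannot type a feature with no observed values")
    distinct = series.unique()
    if len(distinct) <= 2:
        return "binary"
    numeric = pd.to_numeric(series, errors="coerce")
    if numeric.isna().any():
        return "categorical"
    if np.allclose(numeric, np.round(numeric)) and len(distinct) <= 6:
        return "categorical"
    return "numeric"


def univariate_association(
    feature: Sequence[float],
    ltl: Sequence[float],
    kind: str | None = None,
    name: str = "",
) -> AssociationResult:
    """Type-dispatched association between one feature and the LTL outcome.

    Numeric: Kendall tau-b (direction = sign of tau). Categorical:
    Kruskal-Wallis across observed levels (no direction). Binary:
    two-sided rank-sum; direction is the sign of mean LTL in the
    higher-coded level minus the lower. Constant features degenerate to
    p = 1.
    """
    f = pd.Series(list(feature), dtype=float)
    y = pd.Series(list(ltl), dtype=float)
    ok = f.notna() & y.notna()
    f, y = f[ok].to_numpy(), y[ok].to_numpy()
    if f.size < 3:
        raise ValueError("need >=3 complete (feature, ltl) pairs")
    if kind is None:
        kind = classify_feature(f)
    test = _TEST_BY_KIND[kind]
    if np.unique(f).size < 2:
        return AssociationResult(name, test, 0.0, 1.0, 0, int(f.size))
    if kind == "numeric":
        tau, p = stats.kendalltau(f, y)
        return AssociationResult(name, test, float(tau), float(p),
                                 int(np.sign(tau)), int(f.size))
    if kind == "categorical":
        groups = [y[f == level] for level in np.unique(f)]
        groups = [g for g in groups if g.size > 0]
        stat, p = stats.kruskal(*groups)
        return AssociationResult(name, test, float(stat), float(p), 0, int(f.size))
    levels = np.unique(f)
    lo, hi = y[f == levels[0]], y[f == levels[-1]]
    w, p, _ = rank_sum_test(lo, hi)
    direction = int(np.sign(hi.mean() - lo.mean()))
    return AssociationResult(name, test, float(w), float(p), direction, int(f.size))


def screen_features(
    table: StressFeatureTable, ltl: pd.Series
) -> list[AssociationResult]:
    """Univariate screen of every feature against a per-subject outcome."""
    out = []
    y = ltl.reindex(table.data.index)
    for name in table.data.columns:
        out.append(
            univariate_association(table.data[name], y, kind=table.types[name], name=name)
        )
    return out


def impute_median(table: StressFeatureTable) -> StressFeatureTable:
    """Fill missing cells: median for numeric/binary, mode for categorical.

    A binary median is rounded to an observed level; a categorical mode
    tie resolves to the lowest-coded level.
    """
    data = table.data.copy()
    for name in data.columns:
        col = data[name]
        if not col.isna().any():
            continue
        observed = col.dropna()
        kind = table.types[name]
        if kind == "categorical":
            counts = observed.value_counts()
            fill = counts[counts == counts.max()].index.min()
        else:
            fill = observed.median()
            if kind == "binary":
                levels = np.sort(observed.unique())
                fill = levels[np.argmin(np.abs(levels - fill))]
        data[name] = col.fillna(fill)
    return StressFeatureTable(data=data, types=dict(table.types))


def correlation_network(
    table: StressFeatureTable,
    associations: Sequence[AssociationResult],
    embed_seed: int = 0,
    perplexity: float | None = None,
) -> nx.Graph:
    """Feature network: Spearman edges, t-SNE coordinates, screen annotations.

    Nodes carry 2-D coordinates from t-SNE on the rows of the absolute
    Spearman correlation matrix (deterministic for a fixed seed and
    perplexity), size -log10(p), a color class when p < 0.1 (orange for
    positive direction, blue for negative) and a bold flag when
    p < 0.05. Edges join feature pairs with |r| >= 0.3, classed "thick"
    at |r| >= 0.7 and "thin" otherwise.
    """
    data = table.data
    if data.isna().any().any():
        raise ValueError("correlation_network requires an imputed (complete) table")
    by_name = {a.feature: a for a in associations}
    missing = [c for c in data.columns if c not in by_name]
    if missing:
        raise ValueError(f"associations missing for features: {missing[:5]}")
    corr = data.corr(method="spearman")
    constant = data.nunique() <= 1
    if constant.any():
        warnings.warn(
            f"constant features get zero correlation: {list(data.columns[constant])}",
            UserWarning,
            stacklevel=2,
        )
    corr = corr.fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)

    n_features = len(data.columns)
    if perplexity is None:
        perplexity = min(15.0, (n_features - 1) / 3.0)
    coords = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=int(embed_seed),
        init="random",
        max_iter=500,
    ).fit_transform(np.abs(corr.to_numpy()))

    graph = nx.Graph()
    graph.graph.update(
        {"embedding": "tsne", "perplexity": perplexity, "embed_seed": int(embed_seed)}
    )
    for idx, name in enumerate(data.columns):
        a = by_name[name]
        p = max(a.p_value, np.finfo(float).tiny)
        color = None
        if a.p_value < COLOR_P:
            color = "orange" if a.direction > 0 else "blue"
        graph.add_node(
            name,
            x=float(coords[idx, 0]),
            y=float(coords[idx, 1]),
            size=float(-np.log10(p)),
            p_value=float(a.p_value),
            direction=int(a.direction),
            color=color,
            bold=bool(a.p_value < BOLD_P),
            test=a.test,
        )
    cols = list(data.columns)
    for i in range(n_features):
        for j in range(i + 1, n_features):
            r = float(corr.iloc[i, j])
            if abs(r) >= THIN_EDGE_R:
                graph.add_edge(
                    cols[i],
                    cols[j],
                    r=r,
                    weight_class="thick" if abs(r) >= THICK_EDGE_R else "thin",
                )
    return graph


def network_to_json(graph: nx.Graph) -> dict:
    """Node-link JSON form of the feature network."""
    return nx.node_link_data(graph, edges="edges")


def cv_predict(
    table: StressFeatureTable,
    ltl: pd.Series,
    folds: int = 10,
    seed: int = 0,
    n_permutations: int = 100,
) -> CVPredictResult:
    """Cross-validated multivariate prediction of LTL from the stress profile.

    A radial-kernel support vector regression (default regularization,
    standardized inputs) is scored by out-of-fold R2 and MSE under
    ``folds``-fold cross-validation. Significance is judged against a
    permutation null: the outcome is permuted ``n_permutations`` times
    and the observed R2 is called significant only if it exceeds the
    95th percentile of the null R2 distribution.
    """
    y = ltl.reindex(table.data.index)
    keep = y.notna()
    data = table.data.loc[keep]
    y = y.loc[keep].to_numpy(dtype=float)
    n = len(data)
    if folds > n:
        raise ValueError(f"folds={folds} exceeds {n} subjects")
    complete = impute_median(StressFeatureTable(data=data, types=dict(table.types)))
    x = complete.data.to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    splitter = KFold(n_splits=folds, shuffle=True, random_state=int(seed))
    splits = list(splitter.split(x))

    def oof_metrics(outcome: np.ndarray) -> tuple[float, float]:
        pred = np.empty_like(outcome)
        for train, test in splits:
            model = make_pipeline(StandardScaler(), SVR(kernel="rbf"))
            model.fit(x[train], outcome[train])
            pred[test] = model.predict(x[test])
        resid = outcome - pred
        mse = float(np.mean(resid**2))
        ss_tot = float(np.sum((outcome - outcome.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        return r2, mse

    r2, mse = oof_metrics(y)
    null_r2 = np.array(
        [oof_metrics(rng.permutation(y))[0] for _ in range(n_permutations)]
    )
    if n_permutations == 0:
        p_value, significant = 1.0, False
    else:
        p_value = float((1 + np.sum(null_r2 >= r2)) / (1 + n_permutations))
        significant = bool(r2 > np.percentile(null_r2, 95))
    return CVPredictResult(r2=r2, mse=mse, null_r2=null_r2, p_value=p_value,
                           significant=significant)
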