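"""Rank-based group comparisons and the clustered class-average map.

Descriptor distributions across phenotype classes are non-normal and
the groups are badly unbalanced, so group differences are tested with
the Kruskal-Wallis H test (ANOVA on ranks) followed by Dunn's post-hoc
pairwise z-tests, which are valid for unequal group sizes. Class-level
structure is summarized as a clustered map: per-class feature means,
z-scaled per feature across classes (units of standard deviations from
the feature mean), with Euclidean-distance hierarchical clustering of
the class rows and feature columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

logger = logging.getLogger(__name__)

__all__ = ["GroupComparison", "ClassAverageMap", "kruskal_dunn", "kruskal_dunn_table", "class_average_map"]


@dataclass
class GroupComparison:
    """Kruskal-Wallis H with Dunn's pairwise z/p matrices.

    ``dunn_p`` holds unadjusted two-sided p-values, ``dunn_p_adjusted``
    the Holm-corrected ones; both are symmetric with unit diagonal.
    """

    h_stat: float
    p_value: float
    groups: list
    group_sizes: list[int]
    dunn_z: pd.DataFrame
    dunn_p: pd.DataFrame
    dunn_p_adjusted: pd.DataFrame


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment (monotone, capped at 1)."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj


def kruskal_dunn(groups: dict | list, alpha: float = 0.05) -> GroupComparison:
    """ANOVA on ranks with Dunn's post-hoc pairwise comparisons.

    ``groups`` is a mapping name -> values or a list of value arrays.
    H carries the standard tie correction and is referred to the
    chi-square distribution with k-1 df. Dunn z-statistics use the
    pooled-rank variance with tie correction; all values identical
    across every group is the degenerate no-information case (H=0, p=1),
    not an error.
    """
    if isinstance(groups, dict):
        names = list(groups.keys())
        data = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        data = [np.asarray(g, dtype=float) for g in groups]
        names = list(range(len(data)))
    if len(data) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in data):
        raise ValueError("every group needs at least 1 value")

    pooled = np.concatenate(data)
    n_total = len(pooled)
    k = len(data)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
        z = np.zeros((k, k))
        pmat = np.ones((k, k))
    else:
        h, p = stats.kruskal(*data)
        # Dunn: pairwise z from pooled mean ranks
        ranks = stats.rankdata(pooled)
        sizes = np.array([len(g) for g in data])
        bounds = np.cumsum(sizes)
        mean_ranks = np.array(
            [ranks[lo:hi].mean() for lo, hi in zip(np.r_[0, bounds[:-1]], bounds)]
        )
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
        base_var = n_total * (n_total + 1) / 12.0 - tie_term
        z = np.zeros((k, k))
        pmat = np.ones((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
                zij = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
                z[i, j] = zij
                z[j, i] = -zij
                pmat[i, j] = pmat[j, i] = 2.0 * stats.norm.sf(abs(zij))

    iu = np.triu_indices(k, 1)
    adj_flat = _holm(pmat[iu])
    padj = np.ones((k, k))
    padj[iu] = adj_flat
    padj.T[iu] = adj_flat

    as_df = lambda m: pd.DataFrame(m, index=names, columns=names)
    return GroupComparison(
        h_stat=float(h),
        p_value=float(p),
        groups=names,
        group_sizes=[len(g) for g in data],
        dunn_z=as_df(z),
        dunn_p=as_df(pmat),
        dunn_p_adjusted=as_df(padj),
    )


def kruskal_dunn_table(
    table: pd.DataFrame, label_col: str = "class_id", feature_cols: list[str] | None = None
) -> pd.DataFrame:
    """Per-descriptor test summary across classes.

    One row per feature: H, global p, and the smallest Holm-adjusted
    pairwise Dunn p (the strongest pairwise separation) — the tabular
    core of a significance grid over descriptors.
    """
    if feature_cols is None:
        feature_cols = [c for c in table.columns
                        if c not in (label_col, "cell_id", "donor_id")
                        and pd.api.types.is_numeric_dtype(table[c])]
    rows = []
    grouped = {k: g for k, g in table.groupby(label_col)}
    for feat in feature_cols:
        cmp = kruskal_dunn({k: g[feat].to_numpy() for k, g in grouped.items()})
        iu = np.triu_indices(len(cmp.groups), 1)
        rows.append(
            {
                "feature": feat,
                "h_stat": cmp.h_stat,
                "p_value": cmp.p_value,
                "min_pairwise_p_adj": float(cmp.dunn_p_adjusted.to_numpy()[iu].min()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ClassAverageMap:
    """z-scaled class-mean matrix with hierarchical cluster orderings."""

    matrix: pd.DataFrame  # classes x features, z-scaled per feature
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list
    col_order: list
    dropped_features: list[str]


def class_average_map(
    table: pd.DataFrame,
    label_col: str = "class_id",
    feature_cols: list[str] | None = None,
    method: str = "complete",
) -> ClassAverageMap:
    """Clustered map of per-class feature means.

    Class means are z-scaled per feature across classes (population sd,
    n denominator), so each column of the returned matrix has mean 0 and
    sd 1; rows (classes) and columns (features) are ordered by
    ``method``-linkage Euclidean hierarchical clustering. Features whose
    class means have zero variance are excluded (logged). Invariant to
    input row order.
    """
    if feature_cols is None:
        feature_cols = [c for c in table.columns
                        if c not in (label_col, "cell_id", "donor_id")
                        and pd.api.types.is_numeric_dtype(table[c])]
    means = table.groupby(label_col)[feature_cols].mean().sort_index()
    if means.shape[0] < 2 or means.shape[1] < 2:
        raise ValueError("need at least 2 classes and 2 features")
    sd = means.std(axis=0, ddof=0)
    dropped = list(sd.index[sd == 0])
    if dropped:
        logger.info("class_average_map: dropping zero-variance features %s", dropped)
        means = means.drop(columns=dropped)
        sd = sd.drop(index=dropped)
    scaled = (means - means.mean(axis=0)) / sd
    row_link = linkage(scaled.to_numpy(), method=method, metric="euclidean")
    col_link = linkage(scaled.to_numpy().T, method=method, metric="euclidean")
    return ClassAverageMap(
        matrix=scaled,
        row_linkage=row_link,
        col_linkage=col_link,
        row_order=[scaled.index[i] for i in leaves_list(row_link)],
        col_order=[scaled.columns[i] for i in leaves_list(col_link)],
        dropped_features=dropped,
    )
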