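"""Hierarchical classification of diseases from the association matrix.

Diseases are grouped by agglomerative clustering of association-derived
distances, producing a dendrogram whose leaf order defines the heatmap
layout and a flat partition at a chosen cut — the local equivalent of the
heatmap-clustering step many web tools (e.g. ClustVis) perform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import (
    fcluster,
    leaves_list,
    linkage,
    optimal_leaf_ordering,
)
from scipy.spatial.distance import squareform

from .association import AssociationMatrix
from .counts import DiseaseTerm

METRIC_ONE_MINUS = "one-minus-association"
METRIC_CORRELATION = "correlation"

#: Default flat-cut size: diseases group into ~10 affected systems
#: (gastrointestinal, neuronal, eye, cutaneous, musculoskeletal,
#: kidneys-and-lungs, cardiovascular, hematopoietic, endocrine, multiple).
DEFAULT_K = 10


@dataclass
class ClassificationResult:
    """Dendrogram, heatmap leaf order and flat cluster labels."""

    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str]
    flat_labels: dict[str, int]
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if sorted(self.leaf_order) != sorted(self.labels):
            raise ValueError("leaf_order is not a permutation of labels")

    @property
    def n_clusters(self) -> int:
        return len(set(self.flat_labels.values()))

    def linkage_table(self) -> pd.DataFrame:
        """Merge list: children indices, merge height, cluster size."""
        return pd.DataFrame(
            self.linkage, columns=["child_a", "child_b", "height", "size"]
        )


def association_to_distance(
    m: AssociationMatrix, metric: str = METRIC_CORRELATION
) -> np.ndarray:
    """Turn the association matrix into a symmetric distance matrix.

    ``one-minus-association``: d = 1 - a, the direct reading of
    "association distance". ``correlation``: d = 1 - Pearson correlation
    between association *profiles* (matrix rows), with the two diseases'
    own columns excluded pairwise so the conventional diagonal does not
    leak into the profile comparison. A constant profile has no defined
    correlation; its distances are set to the maximum (2) with a warning.
    """
    a = m.values
    n = m.n
    if metric == METRIC_ONE_MINUS:
        d = 1.0 - a
        np.fill_diagonal(d, 0.0)
        return d
    if metric != METRIC_CORRELATION:
        raise ValueError(f"unknown metric {metric!r}")

    if n < 4:
        raise ValueError("correlation metric needs at least 4 diseases")
    d = np.zeros((n, n))
    flagged = set()
    cols = np.arange(n)
    for i in range(n):
        for j in range(i + 1, n):
            keep = (cols != i) & (cols != j)
            x, y = a[i, keep], a[j, keep]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                flagged.add(m.labels[i] if np.ptp(x) == 0 else m.labels[j])
                d[i, j] = d[j, i] = 2.0
                continue
            r = np.corrcoef(x, y)[0, 1]
            d[i, j] = d[j, i] = 1.0 - r
    if flagged:
        warnings.warn(
            f"constant association profile(s) {sorted(flagged)}: "
            "correlation undefined, distances set to 2",
            stacklevel=2,
        )
    # clamp tiny negatives from floating-point in 1 - r
    np.clip(d, 0.0, None, out=d)
    return d


def cluster(
    dist: np.ndarray,
    labels: list[str],
    method: str = "average",
    k: int | None = DEFAULT_K,
    height: float | None = None,
) -> ClassificationResult:
    """Agglomerative clustering with deterministic heatmap leaf order.

    Optimal leaf ordering is applied to the dendrogram so the heatmap
    layout is reproducible; the flat partition cuts at ``k`` clusters
    (default) or at a merge ``height``.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(labels)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if k is not None and k > n:
        raise ValueError(f"k={k} exceeds the number of labels ({n})")

    # sort labels lexicographically first so ties in the linkage are broken
    # identically regardless of input order
    order0 = sorted(range(n), key=lambda i: labels[i])
    labels_sorted = [labels[i] for i in order0]
    dist = dist[np.ix_(order0, order0)]

    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method=method)
    Z = optimal_leaf_ordering(Z, condensed)
    leaf_idx = leaves_list(Z)
    leaf_order = [labels_sorted[i] for i in leaf_idx]

    if height is not None:
        flat = fcluster(Z, t=height, criterion="distance")
    else:
        flat = fcluster(Z, t=k if k is not None else DEFAULT_K, criterion="maxclust")
    return ClassificationResult(
        linkage=Z,
        labels=labels_sorted,
        leaf_order=leaf_order,
        flat_labels={l: int(c) for l, c in zip(labels_sorted, flat)},
        params={"method": method, "k": k, "height": height},
    )


def classify(
    m: AssociationMatrix,
    metric: str = METRIC_CORRELATION,
    method: str = "average",
    k: int | None = DEFAULT_K,
    height: float | None = None,
) -> ClassificationResult:
    """Convenience wrapper: distances then clustering in one call."""
    return cluster(association_to_distance(m, metric), m.labels, method, k, height)


def annotate_clusters(
    result: ClassificationResult, terms: list[DiseaseTerm]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize clusters against term metadata.

    Returns ``(clusters, members)``: a per-cluster table (size, majority
    system label, mean female fraction, mean onset age, mean prevalence)
    and a per-disease table ordered by dendrogram leaf order for heatmap
    rendering. Missing metadata yields missing summary fields.
    """
    by_id = {t.id: t for t in terms}
    rows = []
    for label in result.leaf_order:
        t = by_id.get(label)
        rows.append({
            "id": label,
            "cluster": result.flat_labels[label],
            "system_label": t.system_label if t else None,
            "gender_female_fraction": t.gender_female_fraction if t else None,
            "onset_age": t.onset_age if t else None,
            "prevalence": t.prevalence if t else None,
        })
    members = pd.DataFrame(rows)

    def majority(series: pd.Series):
        s = series.dropna()
        if s.empty:
            return None
        counts = s.value_counts()
        top = counts[counts == counts.iloc[0]]
        return sorted(top.index)[0]  # deterministic tie-break

    clusters = (
        members.groupby("cluster")
        .agg(
            size=("id", "size"),
            majority_system=("system_label", majority),
            mean_female_fraction=("gender_female_fraction", "mean"),
            mean_onset_age=("onset_age", "mean"),
            mean_prevalence=("prevalence", "mean"),
        )
        .reset_index()
    )
    return clusters, members
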