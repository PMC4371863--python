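"""Average-linkage hierarchical clustering of abundance profiles and class averages.

Two uses share one code path: r-protein occupancy profiles across
sucrose-gradient fractions are clustered with Euclidean distance (missing
"gray box" entries handled by pairwise-complete computation), and
pre-aligned EM class-average images are clustered with correlation
distance (1 - Pearson correlation of the flattened pixels).  Group
bookkeeping — which dataset contributed how many particles to each group —
is a simple cross-tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "Dendrogram",
    "GroupAssignment",
    "ClusteringError",
    "hierarchical_cluster",
    "pairwise_distances",
    "group_contribution_histogram",
]


class ClusteringError(ValueError):
    """Input unusable for the requested metric (constant vectors, no overlap)."""


@dataclass
class Dendrogram:
    """Agglomerative tree: scipy-format linkage matrix plus provenance.

    ``merges`` is the (n-1, 4) scipy linkage matrix: each row joins two
    node indices at a merge height; leaves are 0..n-1 in the order of
    ``leaf_ids``.
    """

    merges: np.ndarray
    leaf_ids: list[str]
    metric: str
    linkage_method: str

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def cut(self, n_groups: int | None = None, height: float | None = None) -> "GroupAssignment":
        """Flat partition: exactly ``n_groups`` clusters, or the partition
        whose merges all lie at or below ``height``."""
        if (n_groups is None) == (height is None):
            raise ValueError("specify exactly one of n_groups or height")
        if n_groups is not None:
            flat = fcluster(self.merges, t=n_groups, criterion="maxclust")
        else:
            flat = fcluster(self.merges, t=height, criterion="distance")
        labels = {leaf: f"G{g}" for leaf, g in zip(self.leaf_ids, flat)}
        return GroupAssignment(labels=labels)

    def to_dict(self) -> dict:
        return {
            "format_version": 1,
            "leaf_ids": self.leaf_ids,
            "metric": self.metric,
            "linkage": self.linkage_method,
            "merges": [
                {"left": int(a), "right": int(b), "height": float(h), "size": int(s)}
                for a, b, h, s in self.merges
            ],
        }

    def to_newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}
        nodes = {i: self.leaf_ids[i] for i in range(n)}
        for row_i, (a, b, h, _s) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            node_id = n + row_i
            nodes[node_id] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
            heights[node_id] = h
            del nodes[a], nodes[b]
        (root,) = nodes.values()
        return root + ";"


@dataclass
class GroupAssignment:
    """Item -> group label map, optionally carrying a dataset id per item."""

    labels: dict[str, str]
    dataset_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("assignment must label at least one item")

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"item": k, "group": v, "dataset": self.dataset_ids.get(k, "")}
            for k, v in self.labels.items()
        ]
        return pd.DataFrame(rows)


def _pairwise_complete_euclidean(x: np.ndarray) -> np.ndarray:
    n, m = x.shape
    d = np.zeros((n, n))
    finite = np.isfinite(x)
    for i in range(n):
        for j in range(i + 1, n):
            both = finite[i] & finite[j]
            k = int(both.sum())
            if k < min(2, m):
                raise ClusteringError(
                    f"vectors {i} and {j} share fewer than 2 complete entries"
                )
            diff = x[i, both] - x[j, both]
            # rescale to full length so sparsity does not shrink distances
            d[i, j] = d[j, i] = float(np.sqrt(np.sum(diff**2) * m / k))
    return d


def _correlation_distance(x: np.ndarray) -> np.ndarray:
    if np.any(~np.isfinite(x)):
        raise ClusteringError("correlation metric does not accept missing entries")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = list(np.nonzero(sd == 0)[0])
        raise ClusteringError(f"all-constant vector(s) at index {bad} under correlation metric")
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    corr = z @ z.T / x.shape[1]
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def pairwise_distances(vectors: np.ndarray, metric: str) -> np.ndarray:
    """Square distance matrix under ``euclidean`` (pairwise-complete over
    missing entries) or ``correlation`` (1 - Pearson)."""
    x = np.asarray(vectors, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ClusteringError("need >= 2 equal-length vectors")
    if metric == "euclidean":
        return _pairwise_complete_euclidean(x)
    if metric == "correlation":
        return _correlation_distance(x)
    raise ValueError(f"unknown metric {metric!r}")


def hierarchical_cluster(
    vectors: np.ndarray,
    ids: list[str] | None = None,
    metric: str = "euclidean",
    linkage_method: str = "average",
    n_groups: int | None = None,
    height: float | None = None,
    dataset_ids: dict[str, str] | None = None,
) -> tuple[Dendrogram, GroupAssignment]:
    """Cluster equal-length profiles and cut the tree into groups.

    When neither ``n_groups`` nor ``height`` is given, the tree is cut at
    half the maximum merge height.
    """
    x = np.asarray(vectors, dtype=float)
    if ids is None:
        ids = [f"item{i}" for i in range(len(x))]
    if len(ids) != len(x):
        raise ValueError("ids must match the number of vectors")
    d = pairwise_distances(x, metric)
    condensed = d[np.triu_indices(len(x), k=1)]
    merges = linkage(condensed, method=linkage_method)
    dendro = Dendrogram(merges=merges, leaf_ids=list(ids), metric=metric,
                        linkage_method=linkage_method)
    if n_groups is None and height is None:
        height = 0.5 * float(merges[:, 2].max()) if len(merges) else 0.0
    assignment = dendro.cut(n_groups=n_groups, height=height)
    if dataset_ids:
        assignment.dataset_ids = dict(dataset_ids)
    return dendro, assignment


def group_contribution_histogram(
    assignment: GroupAssignment,
    fractional: bool = False,
    datasets: list[str] | None = None,
) -> pd.DataFrame:
    """Dataset x group counts table (or per-dataset fractions).

    Row sums equal each dataset's item count; in fractional form each row
    sums to 1.  Pass ``datasets`` to include datasets that contributed no
    items (rows of zeros).
    """
    if not assignment.dataset_ids:
        raise ValueError("assignment carries no dataset ids")
    missing = set(assignment.labels) - set(assignment.dataset_ids)
    if missing:
        raise ValueError(f"items without dataset id: {sorted(missing)[:5]}")
    frame = assignment.as_frame()
    table = pd.crosstab(frame["dataset"], frame["group"])
    # keep requested datasets even when they contributed no items
    all_datasets = sorted(set(assignment.dataset_ids.values()) | set(datasets or []))
    table = table.reindex(index=all_datasets, fill_value=0)
    table.index.name = "dataset"
    table.columns.name = "group"
    if fractional:
        sums = table.sum(axis=1)
        table = table.div(sums.replace(0, np.nan), axis=0).fillna(0.0)
    return table
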