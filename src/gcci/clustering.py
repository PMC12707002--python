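"""Ordinal categorization of the 1-D index by exact k-means.

Univariate k-means has a globally optimal solution in which every cluster
is a contiguous interval of the sorted scores; it is found exactly by
dynamic programming over interval split points.  This replaces seeded Lloyd
iteration: deterministic, optimal, no tie ambiguity.

Cluster count is selected by the Calinski-Harabasz pseudo-F

    CH(k) = (B_k / (k - 1)) / (W_k / (n - k)),

where B_k is the between-cluster dispersion (sum of cluster sizes times the
squared distance of the cluster mean from the grand mean) and W_k the
within-cluster dispersion; larger values indicate a better partition.
Clusters are labeled in ascending order of their mean score; for k = 4 the
labels are "least restrictive", "less restrictive", "restrictive",
"most restrictive".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CHResult", "GCCSAssignment", "kmeans_1d", "ch_pseudo_f", "select_k"]

FOUR_LEVEL_LABELS = (
    "least restrictive",
    "less restrictive",
    "restrictive",
    "most restrictive",
)


@dataclass
class CHResult:
    k: int
    n: int
    B: float
    W: float
    value: float  # +inf when W == 0


@dataclass
class GCCSAssignment:
    """Ordinal cluster assignment of communities by index score."""

    community_id: np.ndarray
    score: np.ndarray
    cluster: np.ndarray  # 0-based, ascending mean score
    labels: list[str]  # per-cluster, index = cluster
    cluster_means: np.ndarray
    cluster_sizes: np.ndarray
    ch_by_k: dict[int, CHResult]
    selected_k: int

    @property
    def label_per_community(self) -> list[str]:
        return [self.labels[c] for c in self.cluster]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "community_id": self.community_id,
                "gcci": self.score,
                "cluster": self.cluster,
                "gccs": self.label_per_community,
            }
        )

    def diagnostics_frame(self) -> pd.DataFrame:
        rows = []
        for k in sorted(self.ch_by_k):
            r = self.ch_by_k[k]
            rows.append({"k": k, "calinski_harabasz": r.value, "B": r.B, "W": r.W})
        return pd.DataFrame(rows)


def _interval_costs(xs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Prefix sums enabling O(1) within-SS of any sorted interval."""
    s1 = np.concatenate([[0.0], np.cumsum(xs)])
    s2 = np.concatenate([[0.0], np.cumsum(xs**2)])
    return s1, s2


def _cost(s1: np.ndarray, s2: np.ndarray, i: int, j: int) -> float:
    # within-SS of xs[i..j] inclusive
    n = j - i + 1
    tot = s1[j + 1] - s1[i]
    return (s2[j + 1] - s2[i]) - tot * tot / n


def kmeans_1d(scores: np.ndarray, k: int) -> np.ndarray:
    """Globally optimal 1-D k-means; returns 0-based cluster per score.

    Clusters are numbered in ascending score order.  Ties between equal
    scores are broken by input position (stable sort), so equal scores are
    assigned contiguously and deterministically.
    """
    x = np.asarray(scores, float)
    n = x.size
    if k < 1:
        raise ValueError("k must be at least 1")
    n_distinct = np.unique(x).size
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct score(s)")

    order = np.argsort(x, kind="stable")
    xs = x[order]
    s1, s2 = _interval_costs(xs)

    # D[m, i]: optimal cost of clustering xs[0..i] into m+1 clusters.
    D = np.full((k, n), np.inf)
    split = np.zeros((k, n), dtype=int)  # start index of the last cluster
    for i in range(n):
        D[0, i] = _cost(s1, s2, 0, i)
    for m in range(1, k):
        for i in range(m, n):
            best, best_j = np.inf, m
            for j in range(m, i + 1):
                c = D[m - 1, j - 1] + _cost(s1, s2, j, i)
                if c < best:
                    best, best_j = c, j
            D[m, i] = best
            split[m, i] = best_j

    bounds = np.empty(k + 1, dtype=int)
    bounds[k] = n
    i = n - 1
    for m in range(k - 1, 0, -1):
        j = split[m, i]
        bounds[m] = j
        i = j - 1
    bounds[0] = 0

    labels_sorted = np.empty(n, dtype=int)
    for c in range(k):
        labels_sorted[bounds[c] : bounds[c + 1]] = c
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def ch_pseudo_f(scores: np.ndarray, assignment: np.ndarray) -> CHResult:
    """Calinski-Harabasz pseudo-F of a given partition of 1-D scores."""
    x = np.asarray(scores, float)
    a = np.asarray(assignment)
    n = x.size
    uniq = np.unique(a)
    k = uniq.size
    if k <= 1 or k >= n:
        raise ValueError("CH requires 1 < k < n")
    grand = x.mean()
    B = 0.0
    W = 0.0
    for c in uniq:
        xc = x[a == c]
        m = xc.mean()
        B += xc.size * (m - grand) ** 2
        W += ((xc - m) ** 2).sum()
    if W == 0.0:
        warnings.warn("zero within-cluster dispersion; CH is infinite", stacklevel=2)
        value = np.inf
    else:
        value = (B / (k - 1)) / (W / (n - k))
    return CHResult(k=int(k), n=int(n), B=float(B), W=float(W), value=float(value))


def select_k(
    scores: np.ndarray,
    community_id: np.ndarray | None = None,
    k_range: range | list[int] = range(3, 6),
) -> GCCSAssignment:
    """Fit each candidate k, keep the CH argmax, emit ordinal labels.

    For k = 4 the field vocabulary "least restrictive" ... "most
    restrictive" is used; otherwise labels read "level i of k".  Ties in CH
    prefer the smaller k.
    """
    x = np.asarray(scores, float)
    n = x.size
    if community_id is None:
        community_id = np.arange(1, n + 1)
    n_distinct = np.unique(x).size
    candidates = [k for k in k_range if 2 <= k <= min(n - 1, n_distinct)]
    if not candidates:
        raise ValueError("no valid k in range")

    ch_by_k: dict[int, CHResult] = {}
    assign_by_k: dict[int, np.ndarray] = {}
    for k in candidates:
        a = kmeans_1d(x, k)
        assign_by_k[k] = a
        ch_by_k[k] = ch_pseudo_f(x, a)

    best_k = max(candidates, key=lambda k: (ch_by_k[k].value, -k))
    a = assign_by_k[best_k]
    means = np.array([x[a == c].mean() for c in range(best_k)])
    sizes = np.array([(a == c).sum() for c in range(best_k)])
    # kmeans_1d already numbers clusters in ascending score order
    if best_k == 4:
        labels = list(FOUR_LEVEL_LABELS)
    else:
        labels = [f"level {c + 1} of {best_k}" for c in range(best_k)]
    return GCCSAssignment(
        community_id=np.asarray(community_id),
        score=x,
        cluster=a,
        labels=labels,
        cluster_means=means,
        cluster_sizes=sizes,
        ch_by_k=ch_by_k,
        selected_k=best_k,
    )
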