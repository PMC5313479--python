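"""Staging cut-point estimation from a 1-D distribution of total scores.

Agglomerative (Ward) clustering partitions the observed scores into k
value-contiguous groups; each breakpoint is the midpoint between adjacent
cluster extremes, with an integer boundary following the "stage if total
<= b" convention.  Ward's merge is greedy, so the exact minimum
within-cluster sum of squares over contiguous 1-D partitions — computable
by dynamic programming (Fisher's exact grouping) — is available as an
alternative and serves as the optimality check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage


class CutoffError(ValueError):
    pass


@dataclass
class CutoffEstimate:
    breakpoints: tuple[float, ...]       # midpoints between adjacent clusters
    integer_bounds: tuple[int, ...]      # "stage while total <= b" boundaries
    cluster_sizes: tuple[int, ...]
    anova_f: float
    anova_df: tuple[int, int]
    p_value: float
    effect_size: float                   # epsilon-squared


def cluster_scores(scores, k: int = 4, method: str = "ward") -> np.ndarray:
    """Partition scores into k clusters; labels 0..k-1 ordered by mean.

    ``method="ward"`` runs agglomerative clustering with Ward linkage on
    the 1-D values; ``method="dp"`` computes the exact optimal contiguous
    partition (minimum within-cluster sum of squares) by dynamic
    programming.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 1:
        raise CutoffError("scores must be a 1-D vector")
    if not np.all(np.isfinite(x)):
        raise CutoffError("scores must be finite")
    n = len(x)
    if n < k:
        raise CutoffError(f"need n >= k (n={n}, k={k})")
    if k < 1:
        raise CutoffError("k must be >= 1")
    if k == 1:
        return np.zeros(n, dtype=int)
    if method == "ward":
        z = linkage(x[:, None], method="ward")
        raw = fcluster(z, t=k, criterion="maxclust")
    elif method == "dp":
        raw = _dp_labels(x, k)
    else:
        raise CutoffError(f"unknown method {method!r}")
    # relabel so cluster 0 has the lowest mean
    means = [x[raw == lab].mean() for lab in np.unique(raw)]
    order = np.argsort(means)
    remap = {lab: rank for rank, lab in zip(range(len(order)), np.unique(raw)[order])}
    return np.array([remap[lab] for lab in raw], dtype=int)


def _dp_labels(x: np.ndarray, k: int) -> np.ndarray:
    """Exact min within-SS contiguous partition of sorted values (O(k n^2))."""
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(xs)
    ps = np.concatenate([[0.0], np.cumsum(xs)])
    ps2 = np.concatenate([[0.0], np.cumsum(xs * xs)])

    def seg_cost(i: int, j: int) -> float:  # inclusive i..j on sorted values
        m = j - i + 1
        s = ps[j + 1] - ps[i]
        return (ps2[j + 1] - ps2[i]) - s * s / m

    cost = np.full((k + 1, n + 1), np.inf)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for g in range(1, k + 1):
        for j in range(g, n + 1):
            for i in range(g - 1, j):
                c = cost[g - 1, i] + seg_cost(i, j - 1)
                if c < cost[g, j]:
                    cost[g, j] = c
                    split[g, j] = i
    labels_sorted = np.empty(n, dtype=int)
    j = n
    for g in range(k, 0, -1):
        i = split[g, j]
        labels_sorted[i:j] = g - 1
        j = i
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


def within_ss(scores, labels) -> float:
    """Total within-cluster sum of squares of a labelled partition."""
    x = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    return float(
        sum(((x[labels == lab] - x[labels == lab].mean()) ** 2).sum()
            for lab in np.unique(labels))
    )


def derive_cutoffs(scores, labels) -> CutoffEstimate:
    """Breakpoints between ordered clusters plus one-way ANOVA separation.

    Clusters must be value-contiguous (no overlapping ranges).  Each
    breakpoint is the midpoint between the maximum of cluster j and the
    minimum of cluster j+1; its integer boundary is floor(midpoint), read
    as "the lower stage while total <= b".  Effect size is epsilon-squared.
    """
    x = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if x.shape != labels.shape:
        raise CutoffError("scores and labels must align")
    uniq = np.unique(labels)
    groups = [x[labels == lab] for lab in uniq]
    groups.sort(key=lambda g: g.mean())
    for lo, hi in zip(groups, groups[1:]):
        if lo.max() >= hi.min():
            raise CutoffError(
                f"clusters overlap in value: {lo.max()} >= {hi.min()}"
            )
    breakpoints = tuple(
        float((lo.max() + hi.min()) / 2.0) for lo, hi in zip(groups, groups[1:])
    )
    integer_bounds = tuple(int(math.floor(b)) for b in breakpoints)

    k = len(groups)
    n = len(x)
    if k >= 2 and all(len(g) >= 2 for g in groups) and within_ss(x, labels) > 0:
        f, p = stats.f_oneway(*groups)
        f, p = float(f), float(p)
    else:
        f, p = float("inf"), 0.0
    df = (k - 1, n - k)
    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in groups))
    ms_within = (ss_total - ss_between) / df[1] if df[1] > 0 else 0.0
    eps_sq = (ss_between - df[0] * ms_within) / ss_total if ss_total > 0 else 0.0
    return CutoffEstimate(
        breakpoints=breakpoints,
        integer_bounds=integer_bounds,
        cluster_sizes=tuple(len(g) for g in groups),
        anova_f=f,
        anova_df=df,
        p_value=p,
        effect_size=float(eps_sq),
    )


def estimate_cutoffs(scores, k: int = 4, method: str = "ward") -> CutoffEstimate:
    """Cluster + derive in one call."""
    labels = cluster_scores(scores, k=k, method=method)
    return derive_cutoffs(scores, labels)
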