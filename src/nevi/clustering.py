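"""Vulnerability-profile clustering: complete linkage, gap statistic, profiles.

Tracts are clustered on their subdomain score vectors with agglomerative
hierarchical clustering (Euclidean distance, complete linkage). The number
of clusters is chosen with the gap statistic: for each k the log pooled
within-cluster dispersion of the data is compared to its expectation under
B reference datasets drawn uniformly over each feature's observed range,
and the smallest k satisfying gap(k) >= gap(k+1) - se(k+1) is selected
(the one-standard-error rule). The reference datasets are clustered with
the same hierarchical procedure, so data and null are treated identically.

Pooled within-cluster dispersion is Tibshirani's W_k:

    W_k = sum_r D_r / (2 n_r),   D_r = sum of squared pairwise distances
                                       within cluster r,

which equals the within-cluster sum of squares about cluster centroids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .errors import ParameterError

__all__ = ["GapResult", "ClusterResult", "ProfileHeatmap", "gap_select_k", "cluster_tracts", "cluster_profiles"]


@dataclass
class GapResult:
    """Gap curve and the selected number of clusters."""

    gap: np.ndarray  # gap(k) for k = 1..k_max
    se: np.ndarray  # simulation standard error of gap(k)
    log_w: np.ndarray  # log W_k of the data
    chosen_k: int
    k_max: int
    B: int
    seed: int


@dataclass
class ClusterResult:
    """A flat cut of the complete-linkage tree."""

    labels: pd.Series  # geoid -> cluster label in 1..k
    k: int
    linkage: str = "complete"
    distance: str = "euclidean"
    sizes: dict[int, int] | None = None
    median_overall: dict[int, float] | None = None


@dataclass
class ProfileHeatmap:
    """Cluster-by-subdomain median profile and its feature-standardized companion."""

    medians: pd.DataFrame  # clusters x subdomains, raw median scores
    standardized: pd.DataFrame  # column z-scores across clusters (sample sd)
    median_overall: pd.Series  # per-cluster median overall score
    sizes: pd.Series  # per-cluster tract count


def _labels_for_cut(link: np.ndarray, k: int) -> np.ndarray:
    return fcluster(link, t=k, criterion="maxclust")


def _pooled_within_dispersion(x: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for lab in np.unique(labels):
        pts = x[labels == lab]
        if len(pts) > 1:
            w += float(np.sum(pdist(pts, metric="sqeuclidean"))) / (2.0 * len(pts))
    return w


def _log_w_curve(x: np.ndarray, k_max: int) -> np.ndarray:
    link = linkage(x, method="complete", metric="euclidean")
    return np.array(
        [np.log(max(_pooled_within_dispersion(x, _labels_for_cut(link, k)), 1e-300))
         for k in range(1, k_max + 1)]
    )


def gap_select_k(
    x: pd.DataFrame | np.ndarray, k_max: int = 10, B: int = 100, seed: int = 0
) -> GapResult:
    """Select the number of clusters by the gap statistic (first-SE-max rule).

    ``x`` is the tract-by-subdomain matrix. Reference sets are drawn
    uniformly over each column's observed range. Deterministic given
    ``seed``. Requires ``n > k_max >= 1`` and ``B >= 10``.
    """
    arr = np.asarray(x, dtype=float)
    n = len(arr)
    if k_max < 1 or k_max >= n:
        raise ParameterError(f"need n > k_max >= 1, got n={n}, k_max={k_max}")
    if B < 10:
        raise ParameterError(f"need B >= 10 reference sets, got B={B}")

    log_w = _log_w_curve(arr, k_max)

    rng = np.random.default_rng(seed)
    lo, hi = arr.min(axis=0), arr.max(axis=0)
    ref_log_w = np.empty((B, k_max))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=arr.shape)
        ref_log_w[b] = _log_w_curve(ref, k_max)

    gap = ref_log_w.mean(axis=0) - log_w
    sd = ref_log_w.std(axis=0, ddof=0)
    se = sd * np.sqrt(1.0 + 1.0 / B)

    chosen = k_max
    for k in range(k_max - 1):
        if gap[k] >= gap[k + 1] - se[k + 1]:
            chosen = k + 1
            break
    return GapResult(gap=gap, se=se, log_w=log_w, chosen_k=chosen, k_max=k_max, B=B, seed=seed)


def cluster_tracts(
    x: pd.DataFrame, k: int, overall: pd.Series | None = None
) -> ClusterResult:
    """Complete-linkage agglomerative clustering of tracts, tree cut at k clusters.

    Cluster labels are renumbered 1..k in order of first appearance in the
    input row order, making the labelling deterministic for a fixed table.
    """
    n = len(x)
    if not 1 <= k <= n:
        raise ParameterError(f"need 1 <= k <= n, got k={k}, n={n}")
    arr = np.asarray(x, dtype=float)
    if k == n:
        raw = np.arange(1, n + 1)
    else:
        link = linkage(arr, method="complete", metric="euclidean")
        raw = _labels_for_cut(link, k)

    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[i] = remap[lab]

    series = pd.Series(labels, index=x.index if isinstance(x, pd.DataFrame) else None,
                       name="cluster")
    sizes = series.value_counts().sort_index().to_dict()
    med = None
    if overall is not None:
        med = {int(c): float(overall.loc[series.index[series == c]].median())
               for c in sorted(sizes)}
    return ClusterResult(labels=series, k=int(series.max()), sizes=sizes, median_overall=med)


def cluster_profiles(
    result: ClusterResult, sub: pd.DataFrame, overall: pd.Series
) -> ProfileHeatmap:
    """Median subdomain profile per cluster, plus a feature-standardized matrix.

    The companion matrix z-scores each subdomain's cluster medians across
    clusters (sample sd) to emphasize relative differences; a constant
    column — including the single-cluster case — standardizes to zero.
    """
    labels = result.labels
    medians = sub.groupby(labels).median()
    medians.index.name = "cluster"

    mu = medians.mean(axis=0)
    sd = medians.std(axis=0, ddof=1)
    standardized = (medians - mu).divide(sd.where(sd > 0, np.inf), axis=1).fillna(0.0)

    return ProfileHeatmap(
        medians=medians,
        standardized=standardized,
        median_overall=overall.groupby(labels).median(),
        sizes=labels.value_counts().sort_index(),
    )
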