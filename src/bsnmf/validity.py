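"""Cluster-quality indices and prediction-accuracy measures.

Seven internal quality indices (homogeneity, separation, Dunn index,
average silhouette width, Pearson cophenetic compliance, normalized Hubert
gamma, GAP statistic) and two external measures against known labels
(adjusted Rand index, best-matching accuracy). All pairwise indices accept
either a raw dissimilarity matrix or a :class:`DissimilarityMatrix`.

Conventions adopted where the underlying definitions leave room:

* the comembership (cophenetic) matrix codes 0 = same cluster, 1 =
  different, so that a good partition correlates *positively* with the
  pairwise distances;
* a zero-variance profile contributes 0 to homogeneity; a singleton
  cluster contributes silhouette 0;
* the GAP statistic is returned in the standard Tibshirani orientation
  (higher = better); reporting layers that prefer the lower-is-better
  convention negate it.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .partition import Partition, best_label_matching

__all__ = [
    "DissimilarityMatrix",
    "pairwise_distances",
    "homogeneity",
    "separation",
    "dunn_index",
    "average_silhouette",
    "comembership_matrix",
    "cophenetic_pearson",
    "hubert_gamma",
    "gap_statistic",
    "adjusted_rand",
    "accuracy",
]


@dataclass
class DissimilarityMatrix:
    """Symmetric item × item dissimilarities with a zero diagonal."""

    values: np.ndarray
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"dissimilarity matrix must be square, got {v.shape}")
        if not np.allclose(v, v.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if (v < 0).any():
            raise ValueError("dissimilarities must be non-negative")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("diagonal must be zero")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def pairwise_distances(X, metric: str = "euclidean") -> DissimilarityMatrix:
    """Pairwise distances between the rows of X (items × features)."""
    X = np.asarray(X, dtype=float)
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"unsupported metric {metric!r}")
    d = squareform(pdist(X, metric=metric))
    if metric == "correlation":
        d = np.clip(d, 0.0, None)  # guard tiny negative round-off
        np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(d, metric)


def _as_dissim(D) -> np.ndarray:
    if isinstance(D, DissimilarityMatrix):
        return D.values
    return DissimilarityMatrix(np.asarray(D, dtype=float)).values


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("zero variance; correlation undefined")
    return float((xc @ yc) / denom)


def homogeneity(X, p: Partition) -> float:
    """Mean Pearson correlation between each item and its cluster centroid.

    Items or centroids with a constant profile contribute 0 by convention.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 2:
        raise ValueError(
            "homogeneity needs at least 2 features: the per-item correlation "
            "with its centroid is undefined for single-feature profiles"
        )
    if X.shape[0] != len(p):
        raise ValueError("X rows and partition items differ in count")
    centroids = {k: X[p.assignment == k].mean(axis=0)
                 for k in np.unique(p.assignment)}
    total = 0.0
    for i in range(X.shape[0]):
        x = X[i]
        c = centroids[p.assignment[i]]
        if np.ptp(x) == 0 or np.ptp(c) == 0:
            continue  # contributes 0
        total += _pearson(x, c)
    return total / X.shape[0]


def _cluster_indices(p: Partition) -> dict[int, np.ndarray]:
    return {k: np.flatnonzero(p.assignment == k) for k in np.unique(p.assignment)}


def separation(D, p: Partition) -> float:
    """Minimum single-linkage distance between any two clusters."""
    D = _as_dissim(D)
    groups = _cluster_indices(p)
    if len(groups) < 2:
        raise ValueError("separation needs at least 2 non-empty clusters")
    best = math.inf
    for (ka, ia), (kb, ib) in itertools.combinations(groups.items(), 2):
        best = min(best, D[np.ix_(ia, ib)].min())
    return float(best)


def dunn_index(D, p: Partition) -> float:
    """Min between-cluster distance over max cluster diameter; in [0, +∞].

    Singleton clusters have diameter 0; when every cluster is a singleton
    the index is +∞.
    """
    D = _as_dissim(D)
    groups = _cluster_indices(p)
    if len(groups) < 2:
        raise ValueError("Dunn index needs at least 2 non-empty clusters")
    min_between = separation(D, p)
    max_diam = 0.0
    for idx in groups.values():
        if len(idx) > 1:
            max_diam = max(max_diam, D[np.ix_(idx, idx)].max())
    if max_diam == 0:
        return math.inf
    return float(min_between / max_diam)


def average_silhouette(D, p: Partition) -> float:
    """Mean silhouette width s(i) = (b−a)/max(a, b) over all items.

    ``a(i)`` is the mean dissimilarity to the other members of i's cluster,
    ``b(i)`` the smallest mean dissimilarity to any other cluster. Singleton
    clusters and coincident points (max(a, b) = 0) contribute 0.
    """
    D = _as_dissim(D)
    groups = _cluster_indices(p)
    if len(groups) < 2:
        raise ValueError("silhouette needs at least 2 non-empty clusters")
    s_total = 0.0
    for i in range(len(p)):
        own = p.assignment[i]
        own_idx = groups[own]
        if len(own_idx) == 1:
            continue  # singleton contributes 0
        a = D[i, own_idx[own_idx != i]].mean()
        b = min(D[i, idx].mean() for k, idx in groups.items() if k != own)
        denom = max(a, b)
        if denom > 0:
            s_total += (b - a) / denom
    return s_total / len(p)


def comembership_matrix(p: Partition) -> DissimilarityMatrix:
    """Binary pairwise matrix: 0 if two items share a cluster, 1 otherwise."""
    a = p.assignment
    m = (a[:, None] != a[None, :]).astype(float)
    return DissimilarityMatrix(m, metric="comembership")


def cophenetic_pearson(p: Partition, D) -> float:
    """Pearson correlation between the comembership matrix and D.

    Computed over the N(N−1)/2 upper-triangle pairs; higher values mean the
    partition complies better with the distance structure. Undefined (error)
    when the partition is a single cluster or all singletons.
    """
    D = _as_dissim(D)
    C = comembership_matrix(p).values
    iu = np.triu_indices(len(p), k=1)
    c, d = C[iu], D[iu]
    if c.min() == c.max():
        raise ValueError(
            "comembership matrix has zero variance (single cluster or all "
            "singletons); cophenetic correlation undefined"
        )
    return _pearson(c, d)


def hubert_gamma(p: Partition, D, X) -> float:
    """Normalized Hubert gamma: correlation of distances with centroid distances.

    Pairs (i, j) compare the observed dissimilarity ``D[i, j]`` with the
    Euclidean distance between the centroids of the clusters containing i
    and j (zero when they share a cluster).
    """
    D = _as_dissim(D)
    X = np.asarray(X, dtype=float)
    groups = _cluster_indices(p)
    if len(groups) < 2:
        raise ValueError("Hubert gamma needs at least 2 non-empty clusters")
    centroids = {k: X[idx].mean(axis=0) for k, idx in groups.items()}
    keys = sorted(groups)
    cd = {
        (ka, kb): float(np.linalg.norm(centroids[ka] - centroids[kb]))
        for ka, kb in itertools.product(keys, keys)
    }
    Q = np.array(
        [[cd[(p.assignment[i], p.assignment[j])] for j in range(len(p))]
         for i in range(len(p))]
    )
    iu = np.triu_indices(len(p), k=1)
    q = Q[iu]
    if q.min() == q.max():
        raise ValueError("centroid-distance matrix has zero variance")
    return _pearson(D[iu], q)


def within_dispersion(X, p: Partition) -> float:
    """W_k = Σ_clusters (sum of within-cluster pairwise squared distances)/(2 n_r).

    Equals the total within-cluster sum of squares about the centroids.
    """
    X = np.asarray(X, dtype=float)
    total = 0.0
    for idx in _cluster_indices(p).values():
        if len(idx) < 2:
            continue
        sub = X[idx]
        d2 = squareform(pdist(sub, metric="sqeuclidean")).sum()
        total += d2 / (2 * len(idx))
    return total


def gap_statistic(X, p: Partition | None = None, K: int | None = None,
                  B: int = 50, seed=None, clusterer=None):
    """GAP statistic: log within-dispersion versus a uniform reference.

    ``Gap(K) = mean_b log(W*_kb) − log(W_k)`` with B reference datasets drawn
    uniformly over each feature's observed range and clustered by the same
    procedure (default: K-means). Returns ``(gap, se)`` where ``se`` is the
    reference-dispersion standard error sd·√(1 + 1/B). Higher is better in
    this orientation; negate for the lower-is-better reporting convention.

    ``p`` supplies the observed partition; ``clusterer(X, K, seed)`` may
    override how the reference draws are partitioned.
    """
    X = np.asarray(X, dtype=float)
    if B < 10:
        raise ValueError(f"B must be >= 10, got {B}")
    lo, hi = X.min(axis=0), X.max(axis=0)
    if np.all(hi == lo):
        raise ValueError("degenerate data: every feature is constant")
    if p is None:
        raise ValueError("an observed partition p is required")
    K = K if K is not None else p.K
    w_obs = within_dispersion(X, p)
    if w_obs <= 0:
        raise ValueError(
            "observed within-dispersion is zero (all-singleton or coincident "
            "clusters); GAP undefined"
        )
    if clusterer is None:
        from .decomposition import cluster_kmeans

        def clusterer(data, k, s):
            return cluster_kmeans(data, k, seed=s)

    rng = np.random.default_rng(seed)
    log_refs = np.empty(B)
    for b in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        ref_part = clusterer(ref, K, int(rng.integers(2**31 - 1)))
        w_ref = within_dispersion(ref, ref_part)
        if w_ref <= 0:
            raise ValueError("reference within-dispersion degenerate")
        log_refs[b] = math.log(w_ref)
    gap = float(log_refs.mean() - math.log(w_obs))
    se = float(log_refs.std(ddof=0) * math.sqrt(1 + 1 / B))
    return gap, se


def adjusted_rand(a: Partition, b: Partition) -> float:
    """Adjusted Rand index between two partitions (Hubert–Arabie form).

    1 for identical groupings, approximately 0 in expectation for
    independent partitions; can be negative for adversarial disagreement.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty partition")
    if len(a) != len(b):
        raise ValueError("partitions cover different numbers of items")
    # contingency over observed cluster labels
    la, lb = a.assignment, b.assignment
    table = np.zeros((a.K, b.K), dtype=np.int64)
    for i, j in zip(la, lb):
        table[i - 1, j - 1] += 1
    n = len(a)
    comb = lambda x: x * (x - 1) // 2
    sum_ij = sum(comb(int(v)) for v in table.ravel())
    sum_a = sum(comb(int(v)) for v in table.sum(axis=1))
    sum_b = sum(comb(int(v)) for v in table.sum(axis=0))
    total = comb(n)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0  # both partitions trivial and identical in structure
    return float((sum_ij - expected) / (max_index - expected))


def accuracy(pred: Partition, truth: dict[str, str]) -> float:
    """Fraction of items correctly assigned under the best cluster → class map."""
    _, correct = best_label_matching(pred, truth)
    return correct / len(pred)
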