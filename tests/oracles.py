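"""Independent brute-force reference implementations used only by the tests.

Every function here recomputes a quantity with explicit Python loops (or
exact rational arithmetic) and stays deliberately independent of the
package's vectorized implementations.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def pearson(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))


def homogeneity_loop(X, labels):
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    total = 0.0
    for i in range(len(labels)):
        members = X[labels == labels[i]]
        centroid = members.sum(axis=0) / len(members)
        if np.ptp(X[i]) == 0 or np.ptp(centroid) == 0:
            continue
        total += pearson(X[i], centroid)
    return total / len(labels)


def separation_loop(D, labels):
    D = np.asarray(D, float)
    labels = np.asarray(labels)
    best = math.inf
    for i in range(len(labels)):
        for j in range(len(labels)):
            if labels[i] != labels[j]:
                best = min(best, D[i, j])
    return best


def dunn_loop(D, labels):
    D = np.asarray(D, float)
    labels = np.asarray(labels)
    min_between = separation_loop(D, labels)
    max_diam = 0.0
    for i in range(len(labels)):
        for j in range(len(labels)):
            if labels[i] == labels[j]:
                max_diam = max(max_diam, D[i, j])
    return math.inf if max_diam == 0 else min_between / max_diam


def silhouette_loop(D, labels):
    D = np.asarray(D, float)
    labels = np.asarray(labels)
    n = len(labels)
    total = 0.0
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            continue  # singleton: contributes 0
        a = sum(D[i, j] for j in own) / len(own)
        b = math.inf
        for k in set(labels) - {labels[i]}:
            other = [j for j in range(n) if labels[j] == k]
            b = min(b, sum(D[i, j] for j in other) / len(other))
        if max(a, b) > 0:
            total += (b - a) / max(a, b)
    return total / n


def cophenetic_loop(D, labels):
    D = np.asarray(D, float)
    labels = np.asarray(labels)
    xs, ys = [], []
    for i, j in itertools.combinations(range(len(labels)), 2):
        xs.append(0.0 if labels[i] == labels[j] else 1.0)
        ys.append(D[i, j])
    return pearson(xs, ys)


def hubert_loop(X, D, labels):
    X = np.asarray(X, float)
    D = np.asarray(D, float)
    labels = np.asarray(labels)
    centroids = {k: X[labels == k].mean(axis=0) for k in set(labels)}
    ps, qs = [], []
    for i, j in itertools.combinations(range(len(labels)), 2):
        ps.append(D[i, j])
        qs.append(
            float(np.linalg.norm(centroids[labels[i]] - centroids[labels[j]]))
        )
    return pearson(ps, qs)


def ari_pairs(la, lb):
    """Adjusted Rand via explicit pair counting (Hubert–Arabie pair form)."""
    la, lb = np.asarray(la), np.asarray(lb)
    n11 = n00 = n10 = n01 = 0
    for i, j in itertools.combinations(range(len(la)), 2):
        same_a = la[i] == la[j]
        same_b = lb[i] == lb[j]
        if same_a and same_b:
            n11 += 1
        elif same_a:
            n10 += 1
        elif same_b:
            n01 += 1
        else:
            n00 += 1
    num = 2 * (n11 * n00 - n10 * n01)
    den = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    return 1.0 if den == 0 else num / den


def accuracy_enumerate(pred, truth):
    """Best correct count over every injective cluster -> class mapping."""
    clusters = sorted(set(pred))
    classes = sorted(set(truth))
    r = min(len(clusters), len(classes))
    best = 0
    for subset in itertools.combinations(clusters, r):
        for perm in itertools.permutations(classes, r):
            mapping = dict(zip(subset, perm))
            correct = sum(
                1 for p, t in zip(pred, truth) if mapping.get(p) == t
            )
            best = max(best, correct)
    return best


def hypergeom_tail_exact(N, K, n, k):
    """P(X >= k) for a hypergeometric draw, in exact rational arithmetic."""
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, j) * math.comb(N - K, n - j),
                          math.comb(N, n))
    return total


def within_dispersion_loop(X, labels):
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    total = 0.0
    for k in set(labels):
        idx = [i for i in range(len(labels)) if labels[i] == k]
        d2 = 0.0
        for i in idx:
            for j in idx:
                d2 += float(((X[i] - X[j]) ** 2).sum())
        total += d2 / (2 * len(idx))
    return total


def random_partition(rng, n, k):
    """Random assignment guaranteeing every cluster 1..k is non-empty."""
    labels = np.concatenate([np.arange(1, k + 1),
                             rng.integers(1, k + 1, size=n - k)])
    rng.shuffle(labels)
    return labels
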