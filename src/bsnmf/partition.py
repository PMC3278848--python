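"""Cluster partitions derived from factor matrices, label matching and voting.

A sample belongs to the metagene with the largest entry in its H column; a
gene belongs to the metagene with the largest coefficient in its W row.
Signed baseline factors (SVD/PCA/ICA) use the same rule on magnitudes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "Partition",
    "assign_samples",
    "assign_genes",
    "best_label_matching",
    "voting_consensus",
]


@dataclass
class Partition:
    """Assignment of items to clusters 1..K.

    ``assignment[i]`` is the 1-based cluster of ``item_ids[i]``. Empty
    clusters are permitted but surfaced through :attr:`empty_clusters`.
    """

    item_ids: list[str]
    assignment: np.ndarray
    K: int
    source: str = ""
    true_labels: dict[str, str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.item_ids = [str(i) for i in self.item_ids]
        self.assignment = np.asarray(self.assignment, dtype=int)
        if len(self.item_ids) != len(self.assignment):
            raise ValueError("item_ids and assignment lengths differ")
        if len(self.assignment) == 0:
            raise ValueError("empty partition")
        if self.assignment.min() < 1 or self.assignment.max() > self.K:
            raise ValueError(
                f"cluster indices must lie in 1..{self.K}, got range "
                f"[{self.assignment.min()}, {self.assignment.max()}]"
            )

    def __len__(self) -> int:
        return len(self.item_ids)

    @property
    def empty_clusters(self) -> list[int]:
        used = set(self.assignment.tolist())
        return [k for k in range(1, self.K + 1) if k not in used]

    def members(self, k: int) -> list[str]:
        return [i for i, a in zip(self.item_ids, self.assignment) if a == k]

    def relabel(self, mapping: dict[int, int]) -> "Partition":
        """Return a copy with cluster indices renamed through ``mapping``."""
        new = np.array([mapping[a] for a in self.assignment])
        return Partition(list(self.item_ids), new, self.K, self.source,
                         self.true_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"item_id": self.item_ids, "cluster": self.assignment})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_labels(cls, item_ids, labels: dict[str, str], source="truth") -> "Partition":
        """Build a partition from a class-label map (classes sorted for determinism)."""
        classes = sorted({labels[i] for i in item_ids})
        idx = {c: k for k, c in enumerate(classes, start=1)}
        assignment = np.array([idx[labels[i]] for i in item_ids])
        return cls(list(item_ids), assignment, len(classes), source, dict(labels))


def _argmax_partition(scores: np.ndarray, ids, axis: int, magnitude: bool,
                      source: str) -> Partition:
    """Argmax along ``axis`` with ties broken toward the lowest index."""
    s = np.abs(scores) if magnitude else scores
    winners = np.argmax(s, axis=axis) + 1  # np.argmax returns the first maximum
    k = scores.shape[axis]
    return Partition([str(i) for i in ids], winners, k, source)


def assign_samples(H, sample_ids=None, magnitude: bool = False,
                   source: str = "") -> Partition:
    """Assign sample j to the metagene i with the largest h_ij in column j.

    ``magnitude=True`` uses |h_ij| (for signed SVD/PCA/ICA scores). Ties go
    to the lowest metagene index.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.size == 0:
        raise ValueError("H must be a non-empty 2-D matrix")
    ids = sample_ids if sample_ids is not None else range(H.shape[1])
    return _argmax_partition(H, ids, axis=0, magnitude=magnitude, source=source)


def assign_genes(W, gene_ids=None, magnitude: bool = False,
                 source: str = "") -> Partition:
    """Assign gene i to the metagene j with the largest w_ij in row i."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.size == 0:
        raise ValueError("W must be a non-empty 2-D matrix")
    ids = gene_ids if gene_ids is not None else range(W.shape[0])
    return _argmax_partition(W, ids, axis=1, magnitude=magnitude, source=source)


def _contingency(pred: Partition, truth: dict[str, str]):
    classes = sorted(set(truth[i] for i in pred.item_ids))
    cls_idx = {c: j for j, c in enumerate(classes)}
    table = np.zeros((pred.K, len(classes)), dtype=int)
    for item, k in zip(pred.item_ids, pred.assignment):
        table[k - 1, cls_idx[truth[item]]] += 1
    return table, classes


def best_label_matching(pred: Partition, truth: dict[str, str]):
    """Optimal injective cluster → class matching maximizing correct items.

    Returns ``(mapping, correct)`` where ``mapping`` sends each cluster index
    to a class label or ``None`` (unmatched; all its members count as
    errors). For small K the search is exhaustive; otherwise the optimal
    assignment is found on the contingency table.
    """
    missing = [i for i in pred.item_ids if i not in truth]
    if missing:
        raise ValueError(f"items without a truth label: {missing[:5]}")
    table, classes = _contingency(pred, truth)
    K, L = table.shape

    if K <= 6 and L <= 8:
        best, best_map = -1, None
        r = min(K, L)
        for cluster_subset in itertools.combinations(range(K), r):
            for class_perm in itertools.permutations(range(L), r):
                score = sum(table[c, cl] for c, cl in zip(cluster_subset, class_perm))
                if score > best:
                    best = score
                    best_map = dict(zip(cluster_subset, class_perm))
    else:
        # pad with zero columns so unmatched clusters are representable
        padded = np.hstack([table, np.zeros((K, K), dtype=int)])
        rows, cols = linear_sum_assignment(-padded)
        best_map = {r: c for r, c in zip(rows, cols) if c < L}
        best = int(sum(table[r, c] for r, c in best_map.items()))

    mapping = {k: None for k in range(1, pred.K + 1)}
    for c, cl in best_map.items():
        mapping[c + 1] = classes[cl]
    return mapping, int(best)


def match_partitions(pred: Partition, reference: Partition) -> dict[int, int | None]:
    """Best matching of ``pred``'s clusters onto ``reference``'s clusters."""
    truth = {i: str(a) for i, a in zip(reference.item_ids, reference.assignment)}
    mapping, _ = best_label_matching(pred, truth)
    return {k: (int(v) if v is not None else None) for k, v in mapping.items()}


def voting_consensus(partitions, X=None, D=None, reference_rule="silhouette",
                     reference_index=None) -> Partition:
    """Plurality-vote consensus of several partitions over the same items.

    The reference partition is the input with the highest average silhouette
    width on the supplied data (``X`` items × features, or a precomputed
    dissimilarity ``D``), unless ``reference_index`` picks one explicitly.
    Every other partition is relabeled onto the reference by optimal cluster
    matching; each item then receives its plurality label, with ties (and
    votes from unmatched clusters) resolved to the reference's assignment.
    """
    partitions = list(partitions)
    if not partitions:
        raise ValueError("no partitions given")
    ids0 = partitions[0].item_ids
    K = partitions[0].K
    for p in partitions[1:]:
        if p.item_ids != ids0:
            raise ValueError("partitions cover different item sets")
        if p.K != K:
            raise ValueError("partitions have different K")

    if reference_index is None:
        if reference_rule == "first" or len(partitions) == 1:
            reference_index = 0
        elif reference_rule == "silhouette":
            from .validity import average_silhouette, pairwise_distances

            if D is None:
                if X is None:
                    raise ValueError(
                        "silhouette reference rule needs X or D; pass "
                        "reference_rule='first' to skip it"
                    )
                D = pairwise_distances(X)
            widths = [average_silhouette(D, p) for p in partitions]
            reference_index = int(np.argmax(widths))
        else:
            raise ValueError(f"unknown reference rule {reference_rule!r}")
    ref = partitions[reference_index]

    votes = np.zeros((len(ids0), K + 1), dtype=int)  # column 0 = unmatched
    for idx, p in enumerate(partitions):
        if idx == reference_index:
            aligned = p.assignment
        else:
            mapping = match_partitions(p, ref)
            aligned = np.array([mapping[a] or 0 for a in p.assignment])
        for i, a in enumerate(aligned):
            votes[i, a] += 1

    out = np.empty(len(ids0), dtype=int)
    for i in range(len(ids0)):
        counts = votes[i, 1:]  # unmatched votes never win
        top = counts.max()
        winners = np.flatnonzero(counts == top) + 1
        out[i] = ref.assignment[i] if len(winners) > 1 else winners[0]
    return Partition(list(ids0), out, K, source="voting")
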