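"""Synthetic datasets with the structure the factorization model assumes.

Three generators cover the package's testing needs without any external
download:

* :func:`generate_planted_factors` — the metagene model itself. A rank-K
  product V = W0·H0 is built from block-sparse factors (each gene loads
  dominantly on one metagene, each sample expresses dominantly one
  metagene), Gaussian noise is added and the result clipped at zero. The
  planted gene and sample block labels are returned for recovery scoring.
* :func:`generate_gaussian_clusters` — an Iris-like table: few features,
  K well-separated isotropic Gaussian groups of equal size.
* :func:`generate_annotation_fixture` — GMT-style gene sets, optionally
  biased toward a chosen gene cluster so that enrichment is planted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix, GeneSetCollection
from .partition import Partition

__all__ = [
    "PlantedDataset",
    "generate_planted_factors",
    "generate_gaussian_clusters",
    "generate_annotation_fixture",
]


@dataclass
class PlantedDataset:
    """A planted-structure expression dataset with its generating factors."""

    V: ExpressionMatrix
    true_sample_labels: Partition
    true_gene_labels: Partition
    W0: np.ndarray
    H0: np.ndarray
    noise_sigma: float
    seed: int | None

    @property
    def K(self) -> int:
        return self.true_sample_labels.K


def _block_sizes(total: int, k: int) -> list[int]:
    base, rem = divmod(total, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


def generate_planted_factors(
    N: int = 200,
    M: int = 40,
    K: int = 3,
    noise_sigma: float = 0.1,
    block_overlap: float = 0.1,
    seed=None,
) -> PlantedDataset:
    """Plant a rank-K factor structure V = W0·H0 + noise, clipped at zero.

    Genes are split into K equal blocks; a gene's dominant loading on its
    block metagene is U(0.5, 1.5) and a ``block_overlap`` fraction of genes
    carries a secondary U(0.2, 0.6) loading on the next metagene. Samples
    are split into K blocks; a sample expresses its block metagene at
    U(0.8, 1.2) and the others at a small U(0, 0.1) baseline. Noise is
    i.i.d. N(0, noise_sigma²), and V is clipped at zero so it stays a valid
    non-negative expression matrix (the planted block contrast is ~1 against
    a ~0.1 baseline, so sigma is on the scale of the signal).
    """
    if not K <= min(N, M) / 2:
        raise ValueError(f"need K <= min(N, M)/2; got K={K}, N={N}, M={M}")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if not 0 <= block_overlap <= 1:
        raise ValueError("block_overlap must be in [0, 1]")
    rng = np.random.default_rng(seed)

    gene_labels = np.repeat(np.arange(K), _block_sizes(N, K)) + 1
    sample_labels = np.repeat(np.arange(K), _block_sizes(M, K)) + 1

    W0 = np.zeros((N, K))
    W0[np.arange(N), gene_labels - 1] = rng.uniform(0.5, 1.5, size=N)
    overlap_mask = rng.random(N) < block_overlap
    secondary = gene_labels % K  # 0-based index of the next metagene
    W0[np.flatnonzero(overlap_mask), secondary[overlap_mask]] = rng.uniform(
        0.2, 0.6, size=int(overlap_mask.sum())
    )

    H0 = rng.uniform(0.0, 0.1, size=(K, M))
    H0[sample_labels - 1, np.arange(M)] = rng.uniform(0.8, 1.2, size=M)

    V = W0 @ H0
    if noise_sigma > 0:
        V = V + rng.normal(0.0, noise_sigma, size=V.shape)
    V = np.clip(V, 0.0, None)

    gene_ids = [f"g{i + 1:04d}" for i in range(N)]
    sample_ids = [f"s{j + 1:03d}" for j in range(M)]
    matrix = ExpressionMatrix(V, gene_ids, sample_ids)
    return PlantedDataset(
        V=matrix,
        true_sample_labels=Partition(sample_ids, sample_labels, K, "planted"),
        true_gene_labels=Partition(gene_ids, gene_labels, K, "planted"),
        W0=W0,
        H0=H0,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def generate_gaussian_clusters(
    n_per_class: int = 50,
    n_features: int = 4,
    K: int = 3,
    centers_distance: float = 6.0,
    sigma: float = 1.0,
    seed=None,
):
    """K isotropic Gaussian clusters with centers at mutual distance
    >= ``centers_distance``.

    Returns ``(X, labels)`` with X of shape (K·n_per_class, n_features) and
    ``labels`` mapping item IDs (row order ``i0001``…) to class names
    ``class_1``…``class_K``. For K <= n_features the centers sit on scaled
    coordinate axes (exact mutual distance); otherwise random directions are
    drawn until the spacing constraint holds.
    """
    if centers_distance <= 0:
        raise ValueError("centers_distance must be > 0")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if K < 1 or n_per_class < 1 or n_features < 1:
        raise ValueError("K, n_per_class and n_features must be >= 1")
    rng = np.random.default_rng(seed)

    if K <= n_features:
        centers = np.zeros((K, n_features))
        centers[np.arange(K), np.arange(K)] = centers_distance / np.sqrt(2)
    else:
        radius = centers_distance * np.sqrt(K)
        for _ in range(1000):
            centers = rng.normal(size=(K, n_features))
            centers *= radius / np.linalg.norm(centers, axis=1, keepdims=True)
            diffs = centers[:, None] - centers[None, :]
            d = np.linalg.norm(diffs, axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() >= centers_distance:
                break
        else:  # pragma: no cover - practically unreachable
            raise RuntimeError("could not place well-separated centers")

    X = np.vstack(
        [rng.normal(centers[k], sigma, size=(n_per_class, n_features))
         for k in range(K)]
    )
    ids = [f"i{r + 1:04d}" for r in range(K * n_per_class)]
    labels = {
        ids[r]: f"class_{r // n_per_class + 1}" for r in range(K * n_per_class)
    }
    return X, labels


def generate_annotation_fixture(
    genes,
    n_terms: int = 50,
    enriched_cluster=None,
    enrichment_strength: float = 0.0,
    n_enriched_terms: int | None = None,
    term_size: tuple[int, int] = (10, 40),
    seed=None,
) -> GeneSetCollection:
    """GMT-style gene sets, optionally biased toward one gene cluster.

    Each term draws its members without replacement; with probability
    ``enrichment_strength`` a member of a designated term comes from
    ``enriched_cluster``, otherwise from the whole gene list. Strength 0
    gives a null fixture (uniform sampling, p-values ~ uniform); strength 1
    makes the designated terms cluster-exclusive. ``n_enriched_terms``
    defaults to all terms when a cluster is given.
    """
    genes = [str(g) for g in genes]
    if not genes:
        raise ValueError("gene list is empty")
    if not 0 <= enrichment_strength <= 1:
        raise ValueError("enrichment_strength must be in [0, 1]")
    lo, hi = term_size
    if not 1 <= lo <= hi <= len(genes):
        raise ValueError(f"term_size {term_size} infeasible for {len(genes)} genes")
    cluster = [str(g) for g in (enriched_cluster or [])]
    if enrichment_strength > 0 and not cluster:
        raise ValueError("enrichment_strength > 0 requires an enriched_cluster")
    if n_enriched_terms is None:
        n_enriched_terms = n_terms if cluster else 0
    rng = np.random.default_rng(seed)

    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        biased = t < n_enriched_terms and enrichment_strength > 0
        members: list[str] = []
        chosen: set[str] = set()
        while len(members) < size:
            pool = cluster if (biased and rng.random() < enrichment_strength) else genes
            g = pool[int(rng.integers(len(pool)))]
            if g not in chosen:
                chosen.add(g)
                members.append(g)
        term = f"TERM_{t + 1:04d}"
        sets[term] = members
        descriptions[term] = "planted enriched set" if biased else "background set"
    return GeneSetCollection(sets, descriptions)
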