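"""Hypergeometric gene-set enrichment of gene-wise clusters.

Every annotation term (GO term or pathway alike) is tested against each
gene cluster with the upper-tail hypergeometric probability of drawing at
least the observed number of annotated genes without replacement from the
universe. The universe is the intersection of the expression matrix's
genes with the genes appearing anywhere in the annotation collection.

Summary layers: per-cluster counts of significant terms at ``p < alpha``
(strict), and the weighted score ``q × (−log10 p)`` per term, where ``q``
is the cluster's proportion of significant terms.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import GeneSetCollection
from .partition import Partition

logger = logging.getLogger(__name__)

__all__ = [
    "enrich_cluster",
    "enrich_partition",
    "count_significant",
    "weighted_pvalues",
    "top_ranked_genes",
    "benjamini_hochberg",
]


def enrich_cluster(cluster_genes, term_genes, universe, ease: bool = False) -> float:
    """Upper-tail hypergeometric p-value P(X ≥ k) for one cluster × term pair.

    With universe size N, K_ann annotated genes, cluster size n and overlap
    k, the tail is summed exactly. ``ease=True`` applies the conservative
    EASE-style adjustment (the tail is evaluated at k − 1 successes).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    cluster = set(cluster_genes)
    if not cluster:
        raise ValueError("empty cluster")
    if not cluster <= universe:
        raise ValueError(
            f"cluster contains genes outside the universe: "
            f"{sorted(cluster - universe)[:5]}"
        )
    term = set(term_genes) & universe
    n_univ = len(universe)
    k_ann = len(term)
    n_clust = len(cluster)
    k = len(cluster & term)
    if ease:
        k = max(k - 1, 0)
    if k == 0:
        return 1.0
    # P(X >= k) = survival function at k-1
    return float(hypergeom.sf(k - 1, n_univ, k_ann, n_clust))


def enrich_partition(
    genes_partition: Partition,
    collection: GeneSetCollection,
    alpha: float = 0.05,
    ease: bool = False,
    fdr: bool = False,
) -> pd.DataFrame:
    """Test every (cluster, term) pair; returns one row per pair.

    Columns: cluster, term_id, N (universe size), K_ann, n, k, p_value,
    significant (strict ``p < alpha``, on BH-adjusted values if ``fdr``),
    weighted_score (cluster-level proportion of significant terms times
    −log10 p).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    annotated = collection.all_genes()
    universe = sorted(set(genes_partition.item_ids) & annotated)
    if not universe:
        raise ValueError("universe is empty: no matrix gene appears in the annotation")
    logger.info(
        "enrichment universe: %d of %d matrix genes annotated",
        len(universe), len(genes_partition.item_ids),
    )
    uset = set(universe)
    rows = []
    for k_cluster in sorted(np.unique(genes_partition.assignment)):
        members = [g for g in genes_partition.members(int(k_cluster)) if g in uset]
        if not members:
            logger.warning("cluster %d has no genes in the universe; skipped",
                           k_cluster)
            continue
        cset = set(members)
        for term, term_genes in collection.sets.items():
            tset = set(term_genes) & uset
            k = len(cset & tset)
            p = enrich_cluster(members, term_genes, universe, ease=ease)
            rows.append(
                {
                    "cluster": int(k_cluster),
                    "term_id": term,
                    "N": len(universe),
                    "K_ann": len(tset),
                    "n": len(members),
                    "k": k,
                    "p_value": p,
                }
            )
    result = pd.DataFrame(rows)
    if result.empty:
        raise ValueError("no testable (cluster, term) pairs")
    pcol = result["p_value"]
    if fdr:
        pcol = result.groupby("cluster")["p_value"].transform(
            lambda p: pd.Series(benjamini_hochberg(p.to_numpy()), index=p.index)
        )
        result["p_adjusted"] = pcol
    result["significant"] = pcol < alpha
    q = result.groupby("cluster")["significant"].transform("mean")
    result["weighted_score"] = q * (-np.log10(result["p_value"]))
    return result


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (step-up FDR)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted


def count_significant(results: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Per-cluster counts of terms with p < alpha (strict); index 'total' sums.

    A term counts once per cluster in which it is significant.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    sig = results[results["p_value"] < alpha]
    counts = sig.groupby("cluster").size()
    counts = counts.reindex(sorted(results["cluster"].unique()), fill_value=0)
    counts.loc["total"] = counts.sum()
    return counts


def weighted_pvalues(results: pd.DataFrame, alpha: float = 0.05,
                     top: int | None = None) -> pd.DataFrame:
    """Weighted scores q × (−log10 p) for the terms of a single cluster.

    ``q`` is the proportion of the cluster's tested terms with p < alpha.
    Returns terms ranked by descending score; ``top`` keeps the head (the
    usual display truncates to the top 50).
    """
    if results.empty:
        raise ValueError("no terms tested")
    if results["cluster"].nunique() != 1:
        raise ValueError("weighted_pvalues expects results for a single cluster")
    q = float((results["p_value"] < alpha).mean())
    out = results[["cluster", "term_id", "p_value"]].copy()
    out["proportion_significant"] = q
    out["weighted_score"] = q * (-np.log10(out["p_value"]))
    out = out.sort_values("weighted_score", ascending=False, kind="stable")
    return out.head(top) if top is not None else out


def top_ranked_genes(W, metagene: int, n: int, gene_ids=None) -> list[str]:
    """The n gene IDs with the largest coefficient in one W column.

    ``metagene`` is 1-based; ties are broken by input order. These genes are
    the most explanatory for the corresponding cluster.
    """
    W = np.asarray(W, dtype=float)
    if not 1 <= metagene <= W.shape[1]:
        raise ValueError(f"metagene index must be in 1..{W.shape[1]}, got {metagene}")
    if n > W.shape[0]:
        raise ValueError(f"n={n} exceeds the number of genes {W.shape[0]}")
    ids = [str(g) for g in (gene_ids if gene_ids is not None else range(W.shape[0]))]
    col = W[:, metagene - 1]
    order = np.argsort(-col, kind="stable")[:n]
    return [ids[i] for i in order]
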