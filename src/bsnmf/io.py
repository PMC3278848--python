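"""Readers, writers and preprocessing for expression matrices, labels and gene sets.

Expression data are genes-in-rows, samples-in-columns throughout: entry
``(i, j)`` is the expression of gene *i* in sample *j*. Supported on-disk
formats are plain TSV (header row of sample IDs, first column of gene IDs),
the GCT v1.2 dialect, GMT gene-set files, and two-column label TSVs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_labels",
    "write_labels",
    "read_gmt",
    "write_gmt",
    "filter_low_variance",
    "make_nonnegative",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class ExpressionMatrix:
    """A genes × samples expression matrix with string identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_samples)
        Expression values; units are whatever the source platform used.
    gene_ids : list of str
        Unique row identifiers, in row order.
    sample_ids : list of str
        Unique column identifiers, in column order.
    gene_descriptions : dict, optional
        Side metadata (e.g. the GCT "Description" column), keyed by gene ID.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    gene_descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        n, m = self.values.shape
        if len(self.gene_ids) != n or len(self.sample_ids) != m:
            raise ValueError(
                f"ID lists ({len(self.gene_ids)} genes, {len(self.sample_ids)} "
                f"samples) do not match matrix shape {self.values.shape}"
            )
        if n < 2 or m < 2:
            raise ValueError(f"matrix must be at least 2x2, got {n}x{m}")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        if m > 100 * n:
            warnings.warn(
                f"matrix has {m} samples but only {n} genes; input may be "
                "transposed (expected genes in rows)",
                stacklevel=2,
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. GO terms, pathways) with free-text descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def members(self, term: str) -> list[str]:
        return self.sets[term]

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out.update(genes)
        return out


def _check_unique(ids: list[str], kind: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    if dups:
        raise FormatError(f"duplicate {kind} IDs: {', '.join(dups[:10])}")


def read_expression_matrix(
    path, dialect: str = "tsv", on_missing: str = "reject"
) -> ExpressionMatrix:
    """Read a genes × samples matrix from TSV or GCT v1.2.

    Parameters
    ----------
    path : str or Path
        Input file.
    dialect : {"tsv", "gct"}
        ``tsv``: header row of sample IDs, first column of gene IDs.
        ``gct``: version line ``#1.2``, then a ``<n_genes>\\t<n_samples>``
        line, then a header with NAME and Description columns.
    on_missing : {"reject", "drop"}
        Reject the file on any missing cell, or drop affected gene rows.
    """
    if dialect not in ("tsv", "gct"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if on_missing not in ("reject", "drop"):
        raise ValueError(f"unknown on_missing policy {on_missing!r}")

    descriptions: dict[str, str] = {}
    if dialect == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            dims = fh.readline().split()
            if not version.startswith("#1.2"):
                raise FormatError(f"expected GCT version line '#1.2', got {version!r}")
            try:
                n_decl, m_decl = int(dims[0]), int(dims[1])
            except (IndexError, ValueError) as exc:
                raise FormatError(f"malformed GCT dimension line: {dims!r}") from exc
            df = pd.read_csv(fh, sep="\t", index_col=0, dtype={0: str})
        if "Description" in df.columns:
            descriptions = df["Description"].astype(str).to_dict()
            df = df.drop(columns="Description")
        else:
            raise FormatError("GCT file lacks the Description column")
        if df.shape != (n_decl, m_decl):
            raise FormatError(
                f"GCT preamble declares {n_decl} genes x {m_decl} samples but "
                f"the table has {df.shape[0]} x {df.shape[1]}"
            )
    else:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})

    df.index = df.index.astype(str)
    _check_unique(list(df.index), "gene")

    # locate non-numeric cells precisely before failing
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric value {df.iat[i, j]!r} at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        if on_missing == "reject":
            n_bad = int(numeric.isna().any(axis=1).sum())
            raise FormatError(f"{n_bad} gene rows contain missing values")
        dropped = numeric.index[numeric.isna().any(axis=1)]
        logger.warning("dropped %d gene rows with missing values", len(dropped))
        numeric = numeric.dropna(axis=0)

    m = ExpressionMatrix.from_frame(numeric)
    m.gene_descriptions = {g: descriptions[g] for g in m.gene_ids if g in descriptions}
    return m


def write_expression_matrix(m: ExpressionMatrix, path, dialect: str = "tsv") -> None:
    """Write a matrix as TSV or GCT v1.2 (inverse of :func:`read_expression_matrix`)."""
    df = m.to_frame()
    if dialect == "tsv":
        df.to_csv(path, sep="\t", index_label="gene_id")
    elif dialect == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{m.n_genes}\t{m.n_samples}\n")
            out = df.copy()
            out.insert(0, "Description", [m.gene_descriptions.get(g, "na") for g in m.gene_ids])
            out.to_csv(fh, sep="\t", index_label="NAME")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_labels(path) -> dict[str, str]:
    """Read a two-column TSV of (item_id, class label); a header row is optional."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError("label file must have two tab-separated columns")
    first = df.iloc[0]
    if str(first.iloc[0]).lower() in ("sample_id", "item_id", "id", "sample", "gene_id"):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_labels(labels: dict[str, str], path) -> None:
    pd.DataFrame(
        {"item_id": list(labels), "label": list(labels.values())}
    ).to_csv(path, sep="\t", index=False)


def check_labels_cover(labels: dict[str, str], item_ids: list[str]) -> None:
    """Ensure every labeled item exists among ``item_ids``."""
    extra = set(labels) - set(item_ids)
    if extra:
        raise ValueError(f"labels refer to unknown items: {sorted(extra)[:5]}")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file (term, description, then member gene IDs).

    Duplicate members within a set are removed; empty sets are dropped with
    a warning.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"line {lineno}: expected at least term and description fields"
                )
            term, desc, *genes = fields
            if not term:
                raise FormatError(f"line {lineno}: empty term name")
            members = list(dict.fromkeys(g for g in genes if g))  # dedup, keep order
            if not members:
                logger.warning("GMT line %d: set %r is empty, dropped", lineno, term)
                continue
            sets[term] = members
            descriptions[term] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term, genes in collection.sets.items():
            desc = collection.descriptions.get(term, "na")
            fh.write("\t".join([term, desc, *genes]) + "\n")


def filter_low_variance(
    m: ExpressionMatrix,
    keep_top: int | None = None,
    min_variance: float | None = None,
) -> ExpressionMatrix:
    """Drop low-variance gene rows.

    Exactly one of ``keep_top`` (retain the top-N rows by per-gene sample
    variance, ties broken by input order) or ``min_variance`` (retain rows
    with variance >= threshold) must be given. Surviving rows keep their
    original order.
    """
    if (keep_top is None) == (min_variance is None):
        raise ValueError("give exactly one of keep_top or min_variance")
    variances = m.values.var(axis=1, ddof=0)
    if keep_top is not None:
        if keep_top < 1:
            raise ValueError(f"keep_top must be >= 1, got {keep_top}")
        if keep_top > m.n_genes:
            raise ValueError(f"keep_top={keep_top} exceeds gene count {m.n_genes}")
        # stable sort on -variance: ties resolved by input order
        order = np.argsort(-variances, kind="stable")[:keep_top]
        keep = np.zeros(m.n_genes, dtype=bool)
        keep[order] = True
    else:
        keep = variances >= min_variance
    idx = np.flatnonzero(keep)
    out = ExpressionMatrix(
        m.values[idx], [m.gene_ids[i] for i in idx], list(m.sample_ids)
    )
    out.gene_descriptions = {
        g: m.gene_descriptions[g] for g in out.gene_ids if g in m.gene_descriptions
    }
    return out


def make_nonnegative(m: ExpressionMatrix, mode: str = "reject") -> ExpressionMatrix:
    """Coerce a matrix to be non-negative, as the NMF family requires.

    Modes: ``reject`` errors on any negative value; ``shift`` subtracts the
    (negative) global minimum; ``clip`` zeroes negatives; ``fold`` splits
    each gene row into a positive-part row (suffix ``+``) and a
    negative-part row (suffix ``-``), doubling the row count.
    """
    v = m.values
    if not (v < 0).any():
        return m
    if mode == "reject":
        raise ValueError(
            f"matrix contains negative values (minimum {v.min():g}); "
            "use make_nonnegative with mode 'shift', 'clip' or 'fold'"
        )
    if mode == "shift":
        return ExpressionMatrix(v - v.min(), list(m.gene_ids), list(m.sample_ids))
    if mode == "clip":
        return ExpressionMatrix(np.clip(v, 0, None), list(m.gene_ids), list(m.sample_ids))
    if mode == "fold":
        pos = np.clip(v, 0, None)
        neg = np.clip(-v, 0, None)
        values = np.empty((2 * m.n_genes, m.n_samples))
        values[0::2] = pos
        values[1::2] = neg
        ids: list[str] = []
        for g in m.gene_ids:
            ids.extend([f"{g}+", f"{g}-"])
        return ExpressionMatrix(values, ids, list(m.sample_ids))
    raise ValueError(f"unknown mode {mode!r}")
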