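"""Non-negative matrix factorization family and baseline factorizations.

The expression matrix V (N genes × M samples) is approximated as V ≈ W H
with W (N × C) holding *metagenes* in its columns and H (C × M) holding the
per-sample expression of each metagene. Three estimators implement the
family:

* :class:`NMF` — plain Frobenius-norm multiplicative updates,
* :class:`SparseNMF` — sparseness on H via a ridge-penalized least-squares
  solve of each H column followed by clipping negatives to zero (the
  Gao–Church scheme),
* :class:`BiSparseNMF` — the bi-directional variant alternating the sparse
  H-solve (penalty ``sparsity_h``) with the mirrored sparse W-row solve
  (penalty ``sparsity_w``), so that both metagenes and meta-samples are
  encouraged to be sparse.

All three follow the scikit-learn estimator protocol (``fit``,
``fit_transform``, ``get_params``/``set_params``, trailing-underscore fitted
attributes) but keep the genes × samples orientation of the expression
domain: ``fit(V)`` expects genes in rows, ``fit_transform(V)`` returns W,
and ``transform(V_new)`` projects new sample columns onto the fitted
metagenes, returning their H block.

Module-level functions (:func:`factorize_nmf` et al.) are thin wrappers
returning a :class:`FactorizationResult` record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA, FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.utils import check_random_state

from .io import ExpressionMatrix
from .partition import Partition

_EPS = 1e-12  # multiplicative-update denominator stabilizer

__all__ = [
    "NMF",
    "SparseNMF",
    "BiSparseNMF",
    "FactorizationResult",
    "BaselineFactors",
    "hoyer_sparseness",
    "ridge_nnls_solve",
    "factorize_nmf",
    "factorize_snmf",
    "factorize_bsnmf",
    "factorize_baseline",
    "cluster_kmeans",
]


def hoyer_sparseness(v) -> float:
    """Hoyer sparseness of a vector: (√n − ‖v‖₁/‖v‖₂) / (√n − 1).

    Returns 0 for constant-magnitude vectors and 1 for one-hot vectors.
    Requires a non-zero vector of length ≥ 2.
    """
    v = np.asarray(v, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("sparseness is undefined for vectors of length < 2")
    l2 = np.linalg.norm(v)
    if l2 == 0:
        raise ValueError("sparseness is undefined for the all-zero vector")
    l1 = np.abs(v).sum()
    sqrt_n = np.sqrt(v.size)
    return float((sqrt_n - l1 / l2) / (sqrt_n - 1))


def ridge_nnls_solve(A, b, lam: float):
    """Solve min ½‖b − A x‖² + ½·lam·‖x‖², then clip negatives to zero.

    This is a solve-then-clip scheme, not a true non-negativity-constrained
    least-squares: the unconstrained ridge minimizer
    ``x = (AᵀA + lam·I)⁻¹ Aᵀ b`` is computed first and any negative
    coordinate is then set to zero.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    if lam < 0:
        raise ValueError(f"penalty weight must be >= 0, got {lam}")
    x = _ridge_solve_multi(A, b.reshape(-1, 1) if b.ndim == 1 else b, lam)
    x = np.clip(x, 0.0, None)
    return x[:, 0] if b.ndim == 1 else x

def _ridge_solve_multi(A: np.ndarray, B: np.ndarray, lam: float) -> np.ndarray:
    """Unclipped ridge solutions for every column of B (shared design A)."""
    gram = A.T @ A + lam * np.eye(A.shape[1])
    rhs = A.T @ B
    try:
        return np.linalg.solve(gram, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "ridge system is singular; a positive penalty weight (lam > 0) "
            "makes it well-posed"
        ) from exc


@dataclass
class FactorizationResult:
    """Outcome of one factorization run: factors, penalties and diagnostics."""

    W: np.ndarray
    H: np.ndarray
    C: int
    lambda1: float
    lambda2: float
    objective_trace: np.ndarray
    iterations: int
    converged: bool
    seed: int | None
    method: str
    sparseness_h: float | None = None
    sparseness_w: float | None = None

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])

    def w_frame(self, gene_ids=None) -> pd.DataFrame:
        idx = gene_ids if gene_ids is not None else range(self.W.shape[0])
        return pd.DataFrame(
            self.W, index=idx, columns=[f"metagene_{i + 1}" for i in range(self.C)]
        )

    def h_frame(self, sample_ids=None) -> pd.DataFrame:
        cols = sample_ids if sample_ids is not None else range(self.H.shape[1])
        return pd.DataFrame(
            self.H, index=[f"metagene_{i + 1}" for i in range(self.C)], columns=cols
        )


@dataclass
class BaselineFactors:
    """Factors from a signed baseline (SVD/PCA/ICA); scores may be negative."""

    components: np.ndarray  # N × C gene-side factors
    scores: np.ndarray  # C × M sample-side factors
    method: str
    centered: bool = False
    mean_: np.ndarray | None = field(default=None, repr=False)


def _as_matrix(V) -> np.ndarray:
    if isinstance(V, ExpressionMatrix):
        V = V.values
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {V.shape}")
    return V


def _objective(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    d = V - W @ H
    return float(np.einsum("ij,ij->", d, d))


class _NMFBase(TransformerMixin, BaseEstimator):
    """Shared fit loop scaffolding for the NMF family."""

    def __init__(self, n_components=2, max_iter=2000, tol=1e-5, random_state=None):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # subclasses implement one full iteration, returning updated (W, H)
    def _iterate(self, V, W, H):  # pragma: no cover - abstract
        raise NotImplementedError

    def _init_factors(self, V, rng):
        n, m = V.shape
        c = self.n_components
        # entries in (0, 1]; the uniform draw itself is in [0, 1)
        W = 1.0 - rng.random((n, c))
        H = 1.0 - rng.random((c, m))
        return W, H

    def _validate(self, V):
        V = _as_matrix(V)
        if (V < 0).any():
            raise ValueError(
                f"input contains negative values (min {V.min():g}); apply "
                "bsnmf.io.make_nonnegative first"
            )
        c = self.n_components
        if not 1 <= c < min(V.shape):
            raise ValueError(
                f"n_components must satisfy 1 <= C < min(N, M)="
                f"{min(V.shape)}, got {c}"
            )
        return V

    def fit(self, X, y=None):
        """Factorize the genes × samples matrix X (= V)."""
        V = self._validate(X)
        rng = check_random_state(self.random_state)
        W, H = self._init_factors(V, rng)
        W, H = self._setup(W, H)
        trace = [_objective(V, W, H)]
        converged = False
        n_reinit = 0
        for _ in range(self.max_iter):
            W, H = self._iterate(V, W, H)
            W, H, reinit = self._revive_degenerate(W, H, rng, n_reinit)
            n_reinit += reinit
            trace.append(_objective(V, W, H))
            prev, cur = trace[-2], trace[-1]
            if abs(prev - cur) <= self.tol * max(prev, _EPS):
                converged = True
                break
        self.W_ = W
        self.H_ = H
        self.components_ = H
        self.objective_trace_ = np.asarray(trace)
        self.n_iter_ = len(trace) - 1
        self.converged_ = converged
        self.n_reinit_ = n_reinit
        self.reconstruction_err_ = float(trace[-1])
        return self

    def _setup(self, W, H):
        return W, H

    def _revive_degenerate(self, W, H, rng, n_prior):
        """Reinitialize an all-zero metagene column/row once; warn if it recurs."""
        dead_w = np.flatnonzero(~W.any(axis=0))
        dead_h = np.flatnonzero(~H.any(axis=1))
        n_dead = len(dead_w) + len(dead_h)
        if n_dead == 0:
            return W, H, 0
        if n_prior > 0:
            warnings.warn(
                "degenerate metagene recurred after reinitialization; "
                "consider lowering n_components",
                stacklevel=3,
            )
        W = W.copy()
        H = H.copy()
        for j in dead_w:
            W[:, j] = 1.0 - rng.random(W.shape[0])
        for i in dead_h:
            H[i, :] = 1.0 - rng.random(H.shape[1])
        return W, H, n_dead

    def fit_transform(self, X, y=None):
        """Fit and return the gene-side factor W (N × C)."""
        return self.fit(X).W_

    def transform(self, X):
        """Project new sample columns onto the fitted metagenes.

        Solves each column of X against the fitted W by the same
        ridge-and-clip scheme used during fitting and returns the resulting
        H block (C × n_new_samples).
        """
        V = _as_matrix(X)
        lam = getattr(self, "_h_penalty", 0.0)
        return np.clip(_ridge_solve_multi(self.W_, V, lam), 0.0, None)

    def result_(self, seed=None) -> FactorizationResult:
        """Package fitted attributes as a :class:`FactorizationResult`."""
        h_sp = float(np.mean([hoyer_sparseness(r) for r in self.H_ if r.any()]))
        w_sp = float(np.mean([hoyer_sparseness(c) for c in self.W_.T if c.any()]))
        lam1 = getattr(self, "_h_penalty", 0.0)
        lam2 = getattr(self, "_w_penalty", 0.0)
        return FactorizationResult(
            W=self.W_,
            H=self.H_,
            C=self.n_components,
            lambda1=lam1,
            lambda2=lam2,
            objective_trace=self.objective_trace_,
            iterations=self.n_iter_,
            converged=self.converged_,
            seed=seed,
            method=type(self).__name__.lower(),
            sparseness_h=h_sp,
            sparseness_w=w_sp,
        )


def _normalize_columns(W):
    norms = np.linalg.norm(W, axis=0)
    return W / np.where(norms > 0, norms, 1.0)


def _normalize_rows(H):
    norms = np.linalg.norm(H, axis=1)
    return H / np.where(norms > 0, norms, 1.0)[:, None]


class NMF(_NMFBase):
    """Plain NMF by Frobenius multiplicative updates.

    Minimizes E(W, H) = ‖V − WH‖²_F with the standard element-wise updates
    W ← W ∘ (VHᵀ)/(WHHᵀ) and H ← H ∘ (WᵀV)/(WᵀWH); the objective is
    non-increasing along the trace.
    """

    def _iterate(self, V, W, H):
        W = W * (V @ H.T) / (W @ (H @ H.T) + _EPS)
        H = H * (W.T @ V) / ((W.T @ W) @ H + _EPS)
        return W, H


class SparseNMF(_NMFBase):
    """NMF with a sparseness constraint on H (sample side).

    Each iteration runs the multiplicative W update, rescales the columns of
    W to unit Euclidean norm, then solves every H column by ridge-penalized
    least squares with weight ``sparsity`` and clips negatives to zero.
    """

    def __init__(self, n_components=2, sparsity=0.0, max_iter=2000, tol=1e-5,
                 random_state=None):
        super().__init__(n_components, max_iter, tol, random_state)
        self.sparsity = sparsity

    def _validate(self, V):
        if self.sparsity < 0:
            raise ValueError(f"sparsity must be >= 0, got {self.sparsity}")
        self._h_penalty = float(self.sparsity)
        return super()._validate(V)

    def _setup(self, W, H):
        return _normalize_columns(W), H

    def _iterate(self, V, W, H):
        W = W * (V @ H.T) / (W @ (H @ H.T) + _EPS)
        W = _normalize_columns(W)
        H = np.clip(_ridge_solve_multi(W, V, self._h_penalty), 0.0, None)
        return W, H


class BiSparseNMF(_NMFBase):
    """Bi-directional sparse NMF: sparseness on both H and W.

    Each iteration runs two mirrored half-steps. The H half-step is the
    Gao–Church update (multiplicative W update, W columns rescaled to unit
    norm, ridge-and-clip solve of H columns with weight ``sparsity_h``).
    The W half-step mirrors it on the gene side: multiplicative H update,
    H rows rescaled to unit norm, then every row W_i solved against
    W_i·H ≈ V_i by ridge-and-clip with weight ``sparsity_w``. The recorded
    objective is ‖V − WH‖²_F after each full iteration.
    """

    def __init__(self, n_components=2, sparsity_h=0.0, sparsity_w=0.0,
                 max_iter=2000, tol=1e-5, random_state=None):
        super().__init__(n_components, max_iter, tol, random_state)
        self.sparsity_h = sparsity_h
        self.sparsity_w = sparsity_w

    def _validate(self, V):
        if self.sparsity_h < 0 or self.sparsity_w < 0:
            raise ValueError("sparsity weights must be >= 0")
        self._h_penalty = float(self.sparsity_h)
        self._w_penalty = float(self.sparsity_w)
        return super()._validate(V)

    def _setup(self, W, H):
        return _normalize_columns(W), _normalize_rows(H)

    def _iterate(self, V, W, H):
        # H-side half-step (sparseness on H)
        W = W * (V @ H.T) / (W @ (H @ H.T) + _EPS)
        W = _normalize_columns(W)
        H = np.clip(_ridge_solve_multi(W, V, self._h_penalty), 0.0, None)
        # W-side half-step (sparseness on W); rows of W solved on Hᵀ
        H = H * (W.T @ V) / ((W.T @ W) @ H + _EPS)
        H = _normalize_rows(H)
        W = np.clip(_ridge_solve_multi(H.T, V.T, self._w_penalty), 0.0, None).T
        return W, H


# ---------------------------------------------------------------------------
# functional wrappers


def factorize_nmf(V, C, seed=None, max_iter=2000, tol=1e-5) -> FactorizationResult:
    """Plain NMF of V (genes × samples) into C metagenes."""
    est = NMF(n_components=C, max_iter=max_iter, tol=tol, random_state=seed)
    return est.fit(V).result_(seed=seed)


def factorize_snmf(V, C, lam=0.0, seed=None, max_iter=2000, tol=1e-5) -> FactorizationResult:
    """Sparse NMF (penalty on H) of V into C metagenes."""
    est = SparseNMF(n_components=C, sparsity=lam, max_iter=max_iter, tol=tol,
                    random_state=seed)
    return est.fit(V).result_(seed=seed)


def factorize_bsnmf(V, C, lam1=0.0, lam2=0.0, seed=None, max_iter=2000,
                    tol=1e-5) -> FactorizationResult:
    """Bi-directional sparse NMF of V into C metagenes.

    ``lam1`` weights the H-side (sample) penalty, ``lam2`` the W-side (gene)
    penalty.
    """
    est = BiSparseNMF(n_components=C, sparsity_h=lam1, sparsity_w=lam2,
                      max_iter=max_iter, tol=tol, random_state=seed)
    return est.fit(V).result_(seed=seed)


def factorize_baseline(V, C, method: str, seed=None) -> BaselineFactors:
    """Signed baseline factorization: truncated SVD, PCA or ICA.

    Returns gene-side ``components`` (N × C) and sample-side ``scores``
    (C × M); entries may be negative, so downstream cluster assignment uses
    magnitudes.
    """
    V = _as_matrix(V)
    if not C < min(V.shape):
        raise ValueError(f"C must be < min(N, M)={min(V.shape)}, got {C}")
    if method == "svd":
        u, s, vt = np.linalg.svd(V, full_matrices=False)
        return BaselineFactors(u[:, :C], s[:C, None] * vt[:C], "svd")
    if method == "pca":
        # samples are the observations; gene means removed by the fit
        pca = PCA(n_components=C, random_state=seed)
        scores = pca.fit_transform(V.T).T  # C × M, zero mean per component
        return BaselineFactors(pca.components_.T, scores, "pca", centered=True,
                               mean_=pca.mean_)
    if method == "ica":
        last_err = None
        for attempt in range(5):
            rs = None if seed is None else seed + 1000 * attempt
            ica = FastICA(n_components=C, random_state=rs, max_iter=500)
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                try:
                    sources = ica.fit_transform(V.T)  # M × C
                except ConvergenceWarning as exc:
                    last_err = exc
                    continue
            return BaselineFactors(ica.mixing_, sources.T, "ica", centered=True,
                                   mean_=ica.mean_)
        raise RuntimeError(f"ICA failed to converge after 5 restarts: {last_err}")
    raise ValueError(f"unknown baseline method {method!r}")


def cluster_kmeans(X, K, seed=None, restarts=10) -> Partition:
    """K-means over the rows of X (items × features), best of ``restarts``."""
    X = np.asarray(X, dtype=float)
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    if K > X.shape[0]:
        raise ValueError(f"K={K} exceeds the number of items {X.shape[0]}")
    km = KMeans(n_clusters=K, n_init=restarts, random_state=seed)
    labels = km.fit_predict(X)
    return Partition(
        item_ids=[str(i) for i in range(X.shape[0])],
        assignment=labels + 1,
        K=K,
        source="kmeans",
    )
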