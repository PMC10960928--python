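"""Graph embedding of a Hi-C contact matrix.

Each bin is a node; interaction frequencies are edge weights.  The
embedding proceeds in two stages:

1. *Sparse matrix factorization.*  A negative-sampling proximity matrix
   is built from the random-walk transition probabilities
   ``p_ij = A_ij / D_ii`` and a unigram-style context distribution
   ``P_j ∝ (Σ_i p_ij)^0.75``::

       M_ij = ln p_ij − ln(λ P_j)   on edges,   0 off edges

   and factorized by a randomized truncated SVD; the initial embedding
   is ``Y = U_d Σ_d^{1/2}``.

2. *Spectral propagation.*  With the random-walk Laplacian
   ``L = I − D⁻¹A`` (eigenvalues in [0, 2]) and a band-pass modulator
   ``g(λ) = exp(−½[(λ−μ)² − 1]θ)``, the embedding is refreshed once as

       Y ← D⁻¹A (I − L̃) Y,    L̃ = U g(Λ) U⁻¹.

   ``(I − L̃)Y`` is evaluated through a truncated Chebyshev expansion of
   ``h(λ) = 1 − g(λ)`` on [0, 2], so no eigendecomposition is ever
   formed.  The band-pass keeps mid-spectrum eigenvalues, which carry
   the community (domain) structure, and attenuates the extremes.

The module also reconstructs an artificial contact matrix from the
embeddings (min–max normalized Gram matrix), used to visualize how much
domain structure the embedding recovered from a sparse input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .matrix_io import ContactMatrix

__all__ = [
    "Graph",
    "ProximityMatrix",
    "Embedding",
    "SpectralFilter",
    "build_graph",
    "build_proximity_matrix",
    "sparse_randomized_tsvd",
    "filter_value",
    "chebyshev_coefficients",
    "spectral_propagate",
    "embed",
    "reconstruct_matrix",
]

#: shipped defaults (embedding stage)
DEFAULT_DIM = 128
DEFAULT_LAMBDA_NEG = 1.0
DEFAULT_MU = 0.2
DEFAULT_THETA = 0.5
DEFAULT_CHEB_ORDER = 10


@dataclass
class Graph:
    """Weighted undirected graph from a contact matrix."""

    adjacency: sp.csr_matrix
    degrees: np.ndarray

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        """Unordered pairs (i <= j) with positive weight."""
        return int(sp.triu(self.adjacency, k=0).nnz)

    def transition(self) -> sp.csr_matrix:
        """Row-stochastic D^{-1} A."""
        inv_d = sp.diags(1.0 / self.degrees)
        return (inv_d @ self.adjacency).tocsr()


@dataclass
class ProximityMatrix:
    """Negative-sampling log-ratio proximity matrix M."""

    matrix: sp.csr_matrix
    lambda_neg: float
    context_dist: np.ndarray  # P_j, sums to 1


@dataclass
class Embedding:
    """n x d real matrix, one row per bin."""

    Y: np.ndarray
    provenance: str = "initial"  # {"initial", "propagated"}
    singular_values: np.ndarray | None = None

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.ndim != 2:
            raise ValueError("embedding must be a 2-D array")
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("embedding contains non-finite entries")

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def d(self) -> int:
        return self.Y.shape[1]


@dataclass
class SpectralFilter:
    """Band-pass spectral modulator g(λ) = exp(−½[(λ−μ)² − 1]θ).

    ``g`` peaks at ``λ = μ`` (value ``exp(θ/2)``), equals 1 at
    ``|λ − μ| = 1`` and decays for eigenvalues far from the passband
    center.  ``order`` is the Chebyshev truncation degree used when the
    filter is applied to a Laplacian.
    """

    mu: float = DEFAULT_MU
    theta: float = DEFAULT_THETA
    order: int = DEFAULT_CHEB_ORDER

    def __post_init__(self):
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.order < 1:
            raise ValueError("Chebyshev order must be >= 1")

    def __call__(self, lam):
        lam = np.asarray(lam, dtype=float)
        return np.exp(-0.5 * ((lam - self.mu) ** 2 - 1.0) * self.theta)


def filter_value(f: SpectralFilter, lam) -> float:
    """Evaluate the spectral modulator at eigenvalue ``lam``."""
    return f(lam)


def build_graph(m: ContactMatrix) -> Graph:
    """Contact matrix -> weighted graph; isolated bins get a unit self-loop.

    The self-loop keeps the degree matrix invertible; such bins end up
    with near-zero embeddings and are absorbed into surrounding
    segments, so bin coordinates stay stable.
    """
    A = m.counts.copy().tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    isolated = deg == 0
    if isolated.any():
        A = (A + sp.diags(isolated.astype(float))).tocsr()
        deg = np.asarray(A.sum(axis=1)).ravel()
    return Graph(adjacency=A, degrees=deg)


def build_proximity_matrix(
    g: Graph, lambda_neg: float = DEFAULT_LAMBDA_NEG, clip_negative: bool = True
) -> ProximityMatrix:
    """Negative-sampling proximity matrix over the graph's edges.

    ``M_ij = ln p_ij − ln(λ P_j)`` on edges and 0 elsewhere, with the
    context distribution ``P_j ∝ (Σ_i p_ij)^0.75`` normalized to sum 1.
    Negative entries are clipped to 0 by default (the shifted-PMI
    convention), which also preserves sparsity.
    """
    if lambda_neg <= 0:
        raise ValueError("lambda_neg must be positive")
    if np.any(g.degrees <= 0):
        raise ValueError("all degrees must be positive (run build_graph first)")
    P = g.transition().tocsr()
    col_mass = np.asarray(P.sum(axis=0)).ravel()
    weights = np.power(col_mass, 0.75, where=col_mass > 0, out=np.zeros_like(col_mass))
    context = weights / weights.sum()
    M = P.copy()
    with np.errstate(divide="ignore"):
        M.data = np.log(P.data) - np.log(lambda_neg * context[M.indices])
    if clip_negative:
        M.data = np.maximum(M.data, 0.0)
        M.eliminate_zeros()
    if M.nnz and not np.all(np.isfinite(M.data)):
        raise FloatingPointError("proximity matrix contains non-finite entries")
    return ProximityMatrix(matrix=M.tocsr(), lambda_neg=lambda_neg, context_dist=context)


def sparse_randomized_tsvd(
    pm, d: int, seed: int = 0, oversample: int = 10, power_iters: int = 3
) -> Embedding:
    """Randomized truncated SVD of the proximity matrix.

    A Gaussian range sketch with ``d + oversample`` columns and
    ``power_iters`` subspace iterations reduces the n×n problem to the
    SVD of the small projected matrix ``H = QᵀM``.  Returns the initial
    embedding ``Y = U_d Σ_d^{1/2}``; deterministic given ``seed``.
    """
    M = pm.matrix if isinstance(pm, ProximityMatrix) else sp.csr_matrix(pm)
    n = M.shape[0]
    if not (1 <= d <= n):
        raise ValueError(f"embedding dimension d={d} must satisfy 1 <= d <= n={n}")
    rng = np.random.default_rng(seed)
    k = min(n, d + oversample)
    omega = rng.standard_normal((n, k))
    Q, _ = np.linalg.qr(M @ omega)
    for _ in range(power_iters):
        Q, _ = np.linalg.qr(M.T @ Q)
        Q, _ = np.linalg.qr(M @ Q)
    H = Q.T @ M  # k x n
    Uh, s, _ = np.linalg.svd(np.asarray(H), full_matrices=False)
    U = Q @ Uh[:, :d]
    sigma = s[:d]
    Y = U * np.sqrt(sigma)
    return Embedding(Y=Y, provenance="initial", singular_values=sigma)


def chebyshev_coefficients(func, order: int, n_nodes: int | None = None) -> np.ndarray:
    """Chebyshev expansion coefficients of ``func`` on [0, 2].

    The spectrum of the random-walk Laplacian lives in [0, 2]; we expand
    on ``λ = 1 + x`` with ``x`` on [−1, 1], fitting coefficients by
    discrete cosine projection on Chebyshev nodes.
    """
    N = n_nodes or max(order + 1, 64)
    j = np.arange(N)
    theta = np.pi * (j + 0.5) / N
    x = np.cos(theta)
    fv = np.asarray(func(1.0 + x), dtype=float)
    k = np.arange(order + 1)
    c = (2.0 / N) * (fv[None, :] * np.cos(np.outer(k, theta))).sum(axis=1)
    c[0] /= 2.0
    return c


def _apply_laplacian_poly(P: sp.csr_matrix, Y: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Evaluate Σ c_k T_k(L − I) Y with L = I − P, i.e. T_k(−P) Y."""
    T_prev = Y
    out = coeffs[0] * T_prev
    if len(coeffs) > 1:
        T_cur = -(P @ Y)
        out = out + coeffs[1] * T_cur
        for c in coeffs[2:]:
            T_next = -2.0 * (P @ T_cur) - T_prev
            out = out + c * T_next
            T_prev, T_cur = T_cur, T_next
    return out


def spectral_propagate(e: Embedding, g: Graph, f: SpectralFilter | None) -> Embedding:
    """One propagation step ``Y ← D⁻¹A (I − L̃) Y``.

    ``(I − L̃)Y = h(L)Y`` with ``h = 1 − g`` is computed by a degree
    ``f.order`` Chebyshev polynomial in ``L``; no eigendecomposition is
    formed.  Passing ``f=None`` disables the modulator (``g ≡ 0``) and
    the update reduces to one random-walk smoothing step ``Y ← D⁻¹A Y``.
    """
    if e.Y.shape[0] != g.n:
        raise ValueError("embedding rows must match graph nodes")
    P = g.transition()
    if f is None:
        return Embedding(Y=np.asarray(P @ e.Y), provenance="propagated",
                         singular_values=e.singular_values)
    coeffs = chebyshev_coefficients(lambda lam: 1.0 - f(lam), f.order)
    W = _apply_laplacian_poly(P, e.Y, coeffs)
    return Embedding(Y=np.asarray(P @ W), provenance="propagated",
                     singular_values=e.singular_values)


def embed(
    m: ContactMatrix,
    d: int = DEFAULT_DIM,
    lambda_neg: float = DEFAULT_LAMBDA_NEG,
    f: SpectralFilter | None = None,
    seed: int = 0,
    clip_negative: bool = True,
    propagate: bool = True,
) -> Embedding:
    """Full embedding pipeline for one contact matrix.

    graph -> proximity matrix -> randomized tSVD -> spectral propagation.
    ``d`` is clamped to ``n_bins`` (with a warning) on small inputs.
    Pure function of ``(matrix, parameters, seed)``.
    """
    if f is None:
        f = SpectralFilter()
    g = build_graph(m)
    if d > g.n:
        warnings.warn(f"embedding dimension {d} > n_bins {g.n}; lowering to {g.n}")
        d = g.n
    pm = build_proximity_matrix(g, lambda_neg=lambda_neg, clip_negative=clip_negative)
    e = sparse_randomized_tsvd(pm, d=d, seed=seed)
    if propagate:
        e = spectral_propagate(e, g, f)
    return e


def reconstruct_matrix(e: Embedding) -> np.ndarray:
    """Artificial contact matrix from embeddings.

    ``S = Y Yᵀ`` min–max normalized to [0, 1]; symmetric by
    construction.  A constant Gram matrix (degenerate embedding) maps to
    all 0.5 with a warning.
    """
    S = e.Y @ e.Y.T
    S = (S + S.T) / 2.0
    lo, hi = S.min(), S.max()
    if hi == lo:
        warnings.warn("constant Gram matrix; reconstruction set to 0.5 everywhere")
        return np.full_like(S, 0.5)
    return (S - lo) / (hi - lo)
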