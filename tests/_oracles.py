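"""Independent brute-force oracles used by the test suite.

Everything here recomputes quantities by the most direct route possible
(dense linear algebra, exhaustive dynamic programming, explicit pair
loops) so the fast implementations in the package are checked against
code that shares none of their machinery.
"""

import numpy as np
from scipy.spatial.distance import pdist, squareform


def gram_matrix(Y, kp):
    """Dense kernel Gram matrix, computed directly."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if kp.kernel == "linear":
        return Y @ Y.T
    sq = squareform(pdist(Y, metric="sqeuclidean"))
    return np.exp(-kp.gamma * sq)


def segment_cost_direct(G, a, b):
    """Kernel segment cost from an explicit Gram double sum."""
    sub = G[a:b, a:b]
    return float(np.trace(sub) - sub.sum() / (b - a))


def dp_optimum(Y, beta, kp, min_size=1):
    """Exhaustive O(n^2) dynamic program over all segmentations.

    No pruning; costs come from 2-D prefix sums of the dense Gram
    matrix.  Returns (optimal objective = sum of costs + beta*m,
    changepoint list).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = Y.shape[0]
    G = gram_matrix(Y, kp)
    C = np.zeros((n + 1, n + 1))
    C[1:, 1:] = G.cumsum(axis=0).cumsum(axis=1)
    diag_cum = np.concatenate([[0.0], np.cumsum(np.diag(G))])

    def cost(a, b):
        block = C[b, b] - C[a, b] - C[b, a] + C[a, a]
        return (diag_cum[b] - diag_cum[a]) - block / (b - a)

    F = np.full(n + 1, np.inf)
    F[0] = 0.0
    last = np.full(n + 1, -1, dtype=int)
    for t in range(min_size, n + 1):
        for tau in range(0, t - min_size + 1):
            if not np.isfinite(F[tau]) or (tau != 0 and tau < min_size):
                continue
            val = F[tau] + cost(tau, t) + beta
            if val < F[t] - 1e-12:
                F[t] = val
                last[t] = tau
    cps = []
    t = n
    while t > 0:
        tau = last[t]
        if tau > 0:
            cps.append(tau)
        t = tau
    cps.reverse()
    return float(F[n] - beta), cps


def objective(Y, cps, beta, kp):
    """Objective of a given segmentation, via the direct Gram route."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    G = gram_matrix(Y, kp)
    edges = [0, *list(cps), Y.shape[0]]
    total = sum(segment_cost_direct(G, a, b) for a, b in zip(edges[:-1], edges[1:]))
    return total + beta * len(cps)


def propagate_dense(A, Y, f):
    """Spectral propagation via an explicit eigendecomposition.

    The row-normalized Laplacian L = I − D⁻¹A is similar to the
    symmetric I − D^{-1/2} A D^{-1/2}; the filter is applied in that
    basis and conjugated back, guaranteeing real output.
    """
    A = np.asarray(A, dtype=float)
    deg = A.sum(axis=1)
    d_half = np.sqrt(deg)
    S = np.eye(len(deg)) - A / np.outer(d_half, d_half)
    lam, U = np.linalg.eigh(S)
    h = 1.0 - f(lam)
    hL = (U * h) @ U.T
    hL = (hL / d_half[:, None]) * d_half[None, :]  # back to the L basis
    P = A / deg[:, None]
    return P @ (hL @ Y)


def tad_adj_r2_pairs(dense, domains, max_distance):
    """Per-pair recomputation of the distance-stratified adjusted R²."""
    n = dense.shape[0]
    dom_of = {}
    sizes = []
    for k, (s, e) in enumerate(domains):
        sizes.append(e - s)
        for b in range(s, e):
            dom_of[b] = k
    out = np.full(max_distance, np.nan)
    for g in range(1, max_distance + 1):
        pairs = [(i, i + g) for i in range(n - g)]
        y = np.array([dense[i, j] for i, j in pairs])
        cls = []
        for i, j in pairs:
            di, dj = dom_of.get(i, -1), dom_of.get(j, -1)
            cls.append(di if (di == dj and di >= 0) else -1)
        cls = np.array(cls)
        b = len(pairs)
        p = sum(1 for s in sizes if s > g)
        if b - p - 1 <= 0:
            continue
        yhat = np.empty(b)
        for c in np.unique(cls):
            yhat[cls == c] = y[cls == c].mean()
        ss_res = ((y - yhat) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        if ss_tot == 0:
            out[g - 1] = 1.0 if ss_res == 0 else np.nan
            continue
        out[g - 1] = 1 - (ss_res / (b - p - 1)) / (ss_tot / (b - 1))
    return out
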