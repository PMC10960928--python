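"""Evaluation of TAD-like domain calls.

Partition-similarity scores (mutual information, AMI, MoC), the
distance-stratified TAD-adjR² that asks how much interaction-frequency
variation the domain assignment explains, and cross-cell boundary
statistics: boundary-frequency profiles, consensus boundaries,
shared-boundary counts, flank-normalized signal enrichment at
boundaries, and the frequency-stratified enrichment fold change.

Two sets of domains on the same bin axis are compared by treating the
bins of each domain as one cluster.  With cluster fractions
``p_i = |U_i|/n``, ``q_j = |V_j|/n`` and overlaps ``r_ij = |U_i∩V_j|/n``:

* ``MI(U,V) = Σ_ij r_ij ln(r_ij / (p_i q_j))``
* ``AMI = (MI − E[MI]) / (max(H(U), H(V)) − E[MI])`` with the
  expectation under the fixed-marginals permutation model,
* ``MoC = (Σ_ij r_ij²/(p_i q_j) − 1) / (√(cs) − 1)``, defined as 1 when
  both partitions are a single cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_mutual_info_score

from .matrix_io import ContactMatrix, DomainSet, SignalTrack

__all__ = [
    "Partition",
    "BoundaryFrequencyProfile",
    "partition_from_domains",
    "mutual_information",
    "ami",
    "moc",
    "tad_adj_r2",
    "boundary_frequency",
    "consensus_boundaries",
    "shared_boundary_count",
    "enrichment_profile",
    "frequency_stratified_fold_change",
]


@dataclass
class Partition:
    """Assignment of each of n bins to exactly one cluster."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1 or self.labels.size < 1:
            raise ValueError("labels must be a non-empty 1-D array")

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def n_clusters(self) -> int:
        return np.unique(self.labels).size

    def fractions(self) -> np.ndarray:
        _, counts = np.unique(self.labels, return_counts=True)
        return counts / self.n


@dataclass
class BoundaryFrequencyProfile:
    """Per-bin count of cells whose domain call has a boundary there."""

    counts: np.ndarray
    n_cells: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0) or np.any(self.counts > self.n_cells):
            raise ValueError("counts must lie in [0, n_cells]")

    @property
    def n(self) -> int:
        return self.counts.size


def partition_from_domains(ds: DomainSet) -> Partition:
    """Each domain is one cluster; each maximal contiguous gap run is one
    cluster too (keeps cluster counts comparable to domain counts for
    externally loaded, gappy sets)."""
    labels = np.full(ds.n_bins, -1, dtype=int)
    nxt = 0
    pos = 0
    for s, e in ds.domains:
        if s > pos:  # gap run [pos, s)
            labels[pos:s] = nxt
            nxt += 1
        labels[s:e] = nxt
        nxt += 1
        pos = e
    if pos < ds.n_bins:
        labels[pos:] = nxt
    return Partition(labels=labels)


def _contingency(P: Partition, Q: Partition) -> np.ndarray:
    if P.n != Q.n:
        raise ValueError(f"partition sizes differ: {P.n} vs {Q.n}")
    _, pi = np.unique(P.labels, return_inverse=True)
    _, qi = np.unique(Q.labels, return_inverse=True)
    c, s = pi.max() + 1, qi.max() + 1
    table = np.zeros((c, s))
    np.add.at(table, (pi, qi), 1.0)
    return table / P.n  # r_ij


def mutual_information(P: Partition, Q: Partition) -> float:
    """Natural-log mutual information between two bin partitions."""
    r = _contingency(P, Q)
    p = r.sum(axis=1, keepdims=True)
    q = r.sum(axis=0, keepdims=True)
    mask = r > 0
    return float((r[mask] * np.log(r[mask] / (p @ q)[mask])).sum())


def _entropy(fracs: np.ndarray) -> float:
    fracs = fracs[fracs > 0]
    return float(-(fracs * np.log(fracs)).sum())


def ami(
    P: Partition,
    Q: Partition,
    method: str = "exact",
    n_permutations: int = 200,
    seed: int = 0,
) -> float:
    """Adjusted mutual information, max-entropy normalized.

    ``method="exact"`` uses the closed-form expectation of MI under the
    fixed-marginals (hypergeometric) permutation model;
    ``method="permutation"`` estimates the same expectation by seeded
    Monte-Carlo label shuffling, as a cross-check.  Both partitions
    being a single cluster is the degenerate identity case, scored 1.
    """
    if P.n != Q.n:
        raise ValueError(f"partition sizes differ: {P.n} vs {Q.n}")
    if P.n_clusters == 1 and Q.n_clusters == 1:
        return 1.0
    if method == "exact":
        return float(
            adjusted_mutual_info_score(P.labels, Q.labels, average_method="max")
        )
    if method != "permutation":
        raise ValueError(f"unknown AMI method {method!r}")
    mi = mutual_information(P, Q)
    rng = np.random.default_rng(seed)
    perm_mi = np.empty(n_permutations)
    labels_q = Q.labels.copy()
    for i in range(n_permutations):
        perm_mi[i] = mutual_information(P, Partition(rng.permutation(labels_q)))
    e_mi = perm_mi.mean()
    denom = max(_entropy(P.fractions()), _entropy(Q.fractions())) - e_mi
    if abs(denom) < 1e-15:
        return 1.0 if abs(mi - e_mi) < 1e-15 else 0.0
    return float((mi - e_mi) / denom)


def moc(P: Partition, Q: Partition, printed_normalizer: bool = False) -> float:
    """Measure of concordance between two bin partitions, in [0, 1].

    Defined as 1 when both partitions are a single cluster; otherwise
    ``(Σ_ij r_ij²/(p_i q_j) − 1) / (√(cs) − 1)``.  The alternative
    normalizer ``cs − 1`` is available behind ``printed_normalizer`` for
    comparison; it does not score identical partitions as 1 unless the
    counts match, so the root form is the default.
    """
    r = _contingency(P, Q)
    c, s = r.shape
    if c == 1 and s == 1:
        return 1.0
    p = r.sum(axis=1, keepdims=True)
    q = r.sum(axis=0, keepdims=True)
    mask = r > 0
    total = float((r[mask] ** 2 / (p @ q)[mask]).sum())
    denom = (c * s - 1) if printed_normalizer else (np.sqrt(c * s) - 1.0)
    return float((total - 1.0) / denom)


def tad_adj_r2(m: ContactMatrix, ds: DomainSet, max_distance: int):
    """Distance-stratified adjusted R² of interaction frequencies.

    For each genomic distance ``g`` (in bins, 1..max_distance) the pairs
    ``(i, i+g)`` are grouped: pairs with both bins in one domain take
    that domain's mean IF at distance ``g`` as their fitted value; all
    remaining pairs pool into a single gap class with its own mean.
    With ``b`` pairs and ``p`` domains spanning more than ``g`` bins,

        R²(g) = 1 − [ Σ(Y−Ŷ)² / (b−p−1) ] / [ Σ(Y−Ȳ)² / (b−1) ].

    Distances where ``b − p − 1 <= 0`` (or with zero total variance and
    nonzero residual) are reported as NaN with a warning.  Returns
    ``(per-distance array, nan-mean)``.
    """
    n = m.n_bins
    if not (1 <= max_distance < n):
        raise ValueError(f"max_distance must lie in [1, {n - 1}]")
    # bin -> domain id (or -1 outside every domain)
    dom_of = np.full(n, -1, dtype=int)
    sizes = []
    for k, (s, e) in enumerate(ds.domains):
        dom_of[s:e] = k
        sizes.append(e - s)
    sizes = np.asarray(sizes, dtype=int)

    out = np.full(max_distance, np.nan)
    for g in range(1, max_distance + 1):
        y = np.asarray(m.counts.diagonal(g)).ravel()
        b = y.size
        left, right = dom_of[: n - g], dom_of[g:]
        within = (left == right) & (left >= 0)
        p = int((sizes > g).sum())
        if b - p - 1 <= 0:
            warnings.warn(f"distance {g}: not enough pairs (b={b}, p={p}); skipped")
            continue
        yhat = np.empty(b)
        for dom in np.unique(left[within]):
            sel = within & (left == dom)
            yhat[sel] = y[sel].mean()
        if (~within).any():
            yhat[~within] = y[~within].mean()
        ybar = y.mean()
        ss_res = float(((y - yhat) ** 2).sum())
        ss_tot = float(((y - ybar) ** 2).sum())
        if ss_tot == 0:
            if ss_res == 0:
                out[g - 1] = 1.0
            else:
                warnings.warn(f"distance {g}: zero total variance; skipped")
            continue
        out[g - 1] = 1.0 - (ss_res / (b - p - 1)) / (ss_tot / (b - 1))
    mean = float(np.nanmean(out)) if np.any(np.isfinite(out)) else float("nan")
    return out, mean


def boundary_frequency(sets) -> BoundaryFrequencyProfile:
    """Count, per bin, how many cells place a domain boundary there."""
    sets = list(sets)
    if not sets:
        raise ValueError("need at least one DomainSet")
    n = sets[0].n_bins
    counts = np.zeros(n, dtype=int)
    for ds in sets:
        if ds.n_bins != n:
            raise ValueError("all DomainSets must share n_bins")
        for b in ds.boundaries:
            counts[b] += 1
    return BoundaryFrequencyProfile(counts=counts, n_cells=len(sets))


def consensus_boundaries(
    prof: BoundaryFrequencyProfile, window: int = 2, min_fraction: float = 0.25
):
    """Peaks of the boundary-frequency profile.

    A bin is a consensus boundary when its count is a strict local
    maximum within ±window bins and reaches ``min_fraction`` of the
    cells.  Plateaus have no strict maximum and yield nothing.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    counts = prof.counts
    thr = min_fraction * prof.n_cells
    peaks = []
    for b in range(prof.n):
        if counts[b] < thr or counts[b] == 0:
            continue
        lo, hi = max(0, b - window), min(prof.n, b + window + 1)
        neighbors = np.delete(counts[lo:hi], b - lo)
        if neighbors.size == 0 or counts[b] > neighbors.max():
            peaks.append(b)
    return peaks


def shared_boundary_count(a: DomainSet, b: DomainSet, tolerance: int = 0) -> int:
    """Boundaries of ``a`` matched to distinct boundaries of ``b``
    within ±tolerance bins (greedy left-to-right matching)."""
    if a.n_bins != b.n_bins:
        raise ValueError("DomainSets must share n_bins")
    bb = sorted(b.boundaries)
    used = 0  # boundaries of b before this index are consumed
    count = 0
    for x in sorted(a.boundaries):
        for k in range(used, len(bb)):
            if bb[k] < x - tolerance:
                used = k + 1
                continue
            if bb[k] <= x + tolerance:
                used = k + 1
                count += 1
            break
    return count


def enrichment_profile(
    track: SignalTrack,
    boundaries,
    flank: int,
    bg_inner: int = 100_000,
    bg_outer: int = 500_000,
):
    """Flank-normalized average signal around boundary bins.

    The signal is averaged per offset bin across boundaries over
    ``[−flank, +flank]`` (offsets falling off the chromosome are
    skipped), then the mean over the two background windows —
    ``bg_inner`` to ``bg_outer`` bp up- and downstream — is subtracted.
    Returns ``(offsets in bins, normalized means)``.
    """
    boundaries = list(boundaries)
    if not boundaries:
        raise ValueError("boundary list is empty")
    if flank % track.resolution:
        raise ValueError("flank must be a multiple of the resolution")
    w = flank // track.resolution
    offsets = np.arange(-w, w + 1)
    sums = np.zeros(offsets.size)
    nobs = np.zeros(offsets.size)
    for b in boundaries:
        pos = b + offsets
        ok = (pos >= 0) & (pos < track.n_bins)
        vals = track.values[pos[ok]]
        good = ~np.isnan(vals)
        sums[ok] += np.where(good, vals, 0.0)
        nobs[ok] += good
    with np.errstate(invalid="ignore"):
        means = np.where(nobs > 0, sums / np.maximum(nobs, 1), np.nan)
    bp = np.abs(offsets) * track.resolution
    bg = (bp >= bg_inner) & (bp <= bg_outer)
    if not bg.any():
        raise ValueError("flank too small to contain a background window")
    background = np.nanmean(means[bg])
    return offsets, means - background


def frequency_stratified_fold_change(
    track: SignalTrack, prof: BoundaryFrequencyProfile
) -> dict:
    """Mean signal at bins with boundary frequency f, over the mean at
    bins never called as a boundary, for each observed f >= 1."""
    if track.n_bins != prof.n:
        raise ValueError("track and profile must share n_bins")
    vals = track.values
    zero_mask = (prof.counts == 0) & ~np.isnan(vals)
    if not zero_mask.any():
        raise ValueError("no zero-frequency bins: fold-change denominator undefined")
    base = vals[zero_mask].mean()
    if base == 0:
        raise ValueError("zero mean signal at non-boundary bins")
    out = {}
    for f in np.unique(prof.counts):
        if f == 0:
            continue
        sel = (prof.counts == f) & ~np.isnan(vals)
        if sel.any():
            out[int(f)] = float(vals[sel].mean() / base)
    return out
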