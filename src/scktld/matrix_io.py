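"""Readers, writers and basic containers for binned Hi-C data.

Contact matrices arrive either as sparse upper-triangle COO text
(``bin_i<TAB>bin_j<TAB>count``, 0-based bin indices) or as dense
whitespace-separated square matrices.  Domain sets travel as BED3 with
coordinates in base pairs; per-bin signal tracks as bedGraph-like TSV.
All text I/O is gzip-transparent.

The module also implements the bulk-to-single-cell downsampler: a bulk
contact matrix is expanded into its individual pairwise contacts and a
fixed number of them is drawn uniformly without replacement, emulating
the sparsity of a single cell (~0.35 M contacts).
"""

from __future__ import annotations

import gzip
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "ContactMatrix",
    "DomainSet",
    "SignalTrack",
    "InputError",
    "read_contact_matrix",
    "write_contact_matrix",
    "read_domains",
    "write_domains",
    "read_signal_track",
    "write_signal_track",
    "downsample_contacts",
]


class InputError(ValueError):
    """Malformed or invariant-violating input data."""


def _open_text(path, mode="rt"):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass
class ContactMatrix:
    """Symmetric non-negative binned interaction-frequency matrix.

    Parameters
    ----------
    chrom : str
        Chromosome label.
    resolution : int
        Bin size in base pairs.
    counts : scipy.sparse.csr_matrix
        ``n_bins x n_bins`` symmetric matrix of interaction frequencies.
    """

    chrom: str
    resolution: int
    counts: sp.csr_matrix

    def __post_init__(self):
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts, dtype=float))
        self.counts = self.counts.tocsr().astype(float)
        n, m = self.counts.shape
        if n != m or n < 1:
            raise InputError(f"contact matrix must be square and non-empty, got {n}x{m}")
        if self.resolution < 1:
            raise InputError("resolution must be >= 1 bp")
        data = self.counts.data
        if data.size and (not np.all(np.isfinite(data)) or data.min() < 0):
            raise InputError("contact matrix entries must be finite and non-negative")
        asym = abs(self.counts - self.counts.T)
        if asym.nnz and asym.max() > 1e-8 * max(1.0, abs(data).max() if data.size else 1.0):
            raise InputError("contact matrix must be symmetric")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def total_contacts(self) -> float:
        """Sum over the upper triangle including the diagonal."""
        return float(sp.triu(self.counts, k=0).sum())

    def dense(self) -> np.ndarray:
        return self.counts.toarray()


@dataclass
class DomainSet:
    """Ordered, non-overlapping half-open bin intervals on one chromosome.

    A caller-produced set tiles ``[0, n_bins)`` exactly; externally loaded
    sets may leave gaps between domains.
    """

    chrom: str
    resolution: int
    n_bins: int
    domains: list = field(default_factory=list)

    def __post_init__(self):
        self.domains = [(int(s), int(e)) for s, e in self.domains]
        prev_end = 0
        for s, e in self.domains:
            if not (0 <= s < e <= self.n_bins):
                raise InputError(f"domain [{s}, {e}) outside [0, {self.n_bins})")
            if s < prev_end:
                raise InputError(f"domain [{s}, {e}) overlaps or is out of order")
            prev_end = e

    @property
    def boundaries(self) -> list:
        """Interior domain starts (chromosome ends never count)."""
        return [s for s, _ in self.domains if 0 < s < self.n_bins]

    def tiles(self) -> bool:
        """True when the domains cover [0, n_bins) without gaps."""
        pos = 0
        for s, e in self.domains:
            if s != pos:
                return False
            pos = e
        return pos == self.n_bins


@dataclass
class SignalTrack:
    """One real value per bin (e.g. binned ChIP-seq); NaN marks missing."""

    chrom: str
    resolution: int
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise InputError("signal track must be a non-empty 1-D array")
        finite_or_nan = np.isfinite(self.values) | np.isnan(self.values)
        if not np.all(finite_or_nan):
            raise InputError("signal values must be finite or NaN")

    @property
    def n_bins(self) -> int:
        return self.values.size


def _symmetrize_coo(rows, cols, vals, n_bins):
    """Mirror a single triangle; average where both triangles are stored."""
    raw = sp.coo_matrix((vals, (rows, cols)), shape=(n_bins, n_bins)).tocsr()
    raw.sum_duplicates()
    upper = sp.triu(raw, k=1).tocsr()
    lower_t = sp.tril(raw, k=-1).T.tocsr()
    if upper.nnz and lower_t.nnz:
        mismatch = abs(upper - lower_t)
        if mismatch.nnz and mismatch.max() > 0:
            warnings.warn(
                "both triangles present with unequal values; averaging", stacklevel=3
            )
    num = (upper + lower_t).tocsr()
    den = ((upper != 0).astype(float) + (lower_t != 0).astype(float)).tocsr()
    with np.errstate(divide="ignore"):
        inv = den.copy()
        inv.data = 1.0 / inv.data
    off = num.multiply(inv).tocsr()
    diag = sp.diags(raw.diagonal())
    return (off + off.T + diag).tocsr()


def read_contact_matrix(path, format="coo", resolution=1, n_bins=None, chrom="chr1"):
    """Read a per-chromosome contact matrix from COO or dense text.

    COO rows are ``i<TAB>j<TAB>value`` with 0-based bin indices; either
    triangle (or both) may be stored — the result is always symmetric.
    ``n_bins`` is inferred as ``max index + 1`` unless given.
    """
    if format == "coo":
        rows, cols, vals = [], [], []
        with _open_text(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 3:
                    raise InputError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
                try:
                    i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
                except ValueError as exc:
                    raise InputError(f"{path}:{lineno}: unparsable row ({exc})") from None
                if i < 0 or j < 0:
                    raise InputError(f"{path}:{lineno}: negative bin index")
                if not np.isfinite(v) or v < 0:
                    raise InputError(f"{path}:{lineno}: negative or non-finite count {v}")
                if n_bins is not None and (i >= n_bins or j >= n_bins):
                    raise InputError(
                        f"{path}:{lineno}: bin index >= declared n_bins={n_bins}"
                    )
                rows.append(i)
                cols.append(j)
                vals.append(v)
        if n_bins is None:
            n_bins = (max(max(rows, default=-1), max(cols, default=-1)) + 1) if rows else 1
            n_bins = max(n_bins, 1)
        counts = _symmetrize_coo(
            np.array(rows, dtype=int), np.array(cols, dtype=int),
            np.array(vals, dtype=float), n_bins,
        )
    elif format == "dense":
        with _open_text(path) as fh:
            arr = np.loadtxt(fh, ndmin=2)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise InputError(f"{path}: dense matrix must be square, got {arr.shape}")
        if n_bins is not None and arr.shape[0] != n_bins:
            raise InputError(f"{path}: dense matrix is {arr.shape[0]} bins, expected {n_bins}")
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            bad = int(np.argwhere((arr < 0) | ~np.isfinite(arr))[0][0]) + 1
            raise InputError(f"{path}: negative or non-finite value around row {bad}")
        if not np.allclose(arr, arr.T):
            warnings.warn("dense matrix not symmetric; averaging with its transpose")
        counts = sp.csr_matrix((arr + arr.T) / 2.0)
    else:
        raise InputError(f"unknown contact matrix format {format!r}")
    return ContactMatrix(chrom=chrom, resolution=resolution, counts=counts)


def write_contact_matrix(m: ContactMatrix, path, format="coo"):
    """Write the upper triangle as COO text, or the full dense matrix."""
    if format == "coo":
        upper = sp.triu(m.counts, k=0).tocoo()
        order = np.lexsort((upper.col, upper.row))
        with _open_text(path, "wt") as fh:
            for i, j, v in zip(upper.row[order], upper.col[order], upper.data[order]):
                fh.write(f"{i}\t{j}\t{v:g}\n")
    elif format == "dense":
        with _open_text(path, "wt") as fh:
            np.savetxt(fh, m.dense(), fmt="%g")
    else:
        raise InputError(f"unknown contact matrix format {format!r}")


def write_domains(ds: DomainSet, path):
    """Write a DomainSet as BED3 (0-based, half-open, base-pair coords)."""
    with _open_text(path, "wt") as fh:
        for s, e in ds.domains:
            fh.write(f"{ds.chrom}\t{s * ds.resolution}\t{e * ds.resolution}\n")


def read_domains(path, resolution, n_bins, chrom=None):
    """Read BED3 domains; coordinates must be multiples of ``resolution``."""
    domains = []
    seen_chrom = chrom
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: expected >=3 BED columns")
            c, start, end = parts[0], int(parts[1]), int(parts[2])
            if seen_chrom is None:
                seen_chrom = c
            if start % resolution or end % resolution:
                raise InputError(
                    f"{path}:{lineno}: coordinates not aligned to {resolution} bp bins"
                )
            domains.append((start // resolution, end // resolution))
    domains.sort()
    return DomainSet(chrom=seen_chrom or "chr1", resolution=resolution,
                     n_bins=n_bins, domains=domains)


def read_signal_track(path, resolution, n_bins, chrom=None):
    """Read a bedGraph-like TSV (chrom start end value) into per-bin values."""
    values = np.full(n_bins, np.nan)
    seen_chrom = chrom
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise InputError(f"{path}:{lineno}: expected 4 bedGraph columns")
            c, start, end, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if seen_chrom is None:
                seen_chrom = c
            if start % resolution or end % resolution:
                raise InputError(f"{path}:{lineno}: interval not bin-aligned")
            b0, b1 = start // resolution, end // resolution
            if b1 > n_bins:
                raise InputError(f"{path}:{lineno}: interval beyond n_bins={n_bins}")
            values[b0:b1] = v
    return SignalTrack(chrom=seen_chrom or "chr1", resolution=resolution, values=values)


def write_signal_track(track: SignalTrack, path):
    with _open_text(path, "wt") as fh:
        for b, v in enumerate(track.values):
            if np.isnan(v):
                continue
            fh.write(
                f"{track.chrom}\t{b * track.resolution}\t{(b + 1) * track.resolution}\t{v:g}\n"
            )


def downsample_contacts(m: ContactMatrix, target: int, seed: int) -> ContactMatrix:
    """Uniform without-replacement downsampling of individual contacts.

    The upper triangle (including the diagonal) is conceptually expanded
    into ``N = total_contacts`` individual pairwise interactions; exactly
    ``target`` of them are sampled uniformly without replacement and
    re-binned.  Equivalent to a multivariate hypergeometric draw over the
    non-zero cells.  Requires raw integer counts.
    """
    upper = sp.triu(m.counts, k=0).tocoo()
    vals = upper.data
    rounded = np.rint(vals)
    if vals.size and not np.allclose(vals, rounded, atol=1e-9):
        raise InputError("downsampling requires integer contact counts")
    counts = rounded.astype(np.int64)
    total = int(counts.sum())
    target = int(target)
    if target < 0 or target > total:
        raise InputError(f"target {target} outside [0, N={total}]")
    rng = np.random.default_rng(seed)
    if counts.size:
        new_counts = rng.multivariate_hypergeometric(counts, target, method="marginals")
    else:
        new_counts = counts
    keep = new_counts > 0
    coo = sp.coo_matrix(
        (new_counts[keep].astype(float), (upper.row[keep], upper.col[keep])),
        shape=m.counts.shape,
    ).tocsr()
    off = sp.triu(coo, k=1)
    sym = off + off.T + sp.diags(coo.diagonal())
    return ContactMatrix(chrom=m.chrom, resolution=m.resolution, counts=sym.tocsr())
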