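"""k-mer based genome-size estimation.

The estimator is the classical coverage identity

    G = n_kmer / c_kmer = n_base / c_base,   c_base = c_kmer * L / (L - K + 1)

where ``n_kmer`` is the total number of k-mer observations, ``c_kmer`` the
k-mer coverage depth at the homozygous peak of the multiplicity histogram,
``L`` the mean read length and ``K`` the k-mer size (default 21). Sequencing
errors pile distinct low-multiplicity k-mers into a spike at small
multiplicity; the error trough (first local minimum of the histogram) is
located so those observations can be excluded from ``n_kmer``.

Counting is strand-collapsed (canonical k-mers) and fully vectorised:
reads are concatenated with N separators, per-position 2-bit codes are
accumulated by a Horner scheme, and multiplicities come from ``np.unique``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import _nt
from .io_formats import LongRead

__all__ = [
    "KmerHistogram",
    "GenomeSizeEstimate",
    "count_kmers",
    "find_coverage_peak",
    "estimate_size",
]

#: Multiplicities above this are pooled into one bin (repeat tail).
MULTIPLICITY_CAP = 10_000


@dataclass(frozen=True)
class KmerHistogram:
    """Multiplicity histogram: how many distinct k-mer species occur m times."""

    K: int
    counts: Mapping[int, int]

    def __post_init__(self) -> None:
        if any(m < 1 for m in self.counts):
            raise ValueError("multiplicities must be >= 1")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be >= 0")

    @property
    def n_kmer(self) -> int:
        """Total k-mer observations, sum of m * counts[m]."""
        return int(sum(m * c for m, c in self.counts.items()))

    def dense(self) -> np.ndarray:
        """Counts as a dense array indexed by multiplicity (index 0 unused)."""
        if not self.counts:
            return np.zeros(1, dtype=np.int64)
        arr = np.zeros(max(self.counts) + 1, dtype=np.int64)
        for m, c in self.counts.items():
            arr[m] = c
        return arr


@dataclass(frozen=True)
class GenomeSizeEstimate:
    """Genome size plus the coverage quantities it was derived from."""

    G: int
    c_kmer: float
    c_base: float
    L: float
    K: int
    n_base: float
    n_kmer: int


def count_kmers(
    reads: Sequence[LongRead], K: int, canonical: bool = True
) -> KmerHistogram:
    """Count K-mers over a read set into a multiplicity histogram.

    K-mers containing N are skipped; in canonical mode a k-mer and its
    reverse complement count as one species. Multiplicities above
    ``MULTIPLICITY_CAP`` are pooled at the cap.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > 31:
        raise ValueError("K must be <= 31 (64-bit codes)")
    usable = [r.sequence for r in reads if r.length >= K]
    if not usable:
        return KmerHistogram(K=K, counts={})
    codes = _nt.encode("N".join(usable))
    m = codes.size - K + 1
    x = codes.astype(np.uint64)
    four = np.uint64(4)
    three = np.uint64(3)
    fwd = np.zeros(m, dtype=np.uint64)
    for j in range(K):
        fwd *= four
        fwd += x[j : j + m]
    if canonical:
        rev = np.zeros(m, dtype=np.uint64)
        for j in range(K - 1, -1, -1):
            rev *= four
            rev += three
            rev -= x[j : j + m]
        species = np.minimum(fwd, rev)
    else:
        species = fwd
    bad = (codes >= 4).astype(np.int32)
    cum = np.concatenate([[0], np.cumsum(bad)])
    valid = (cum[K:] - cum[:-K]) == 0
    _, multiplicity = np.unique(species[valid], return_counts=True)
    np.minimum(multiplicity, MULTIPLICITY_CAP, out=multiplicity)
    hist = np.bincount(multiplicity)
    return KmerHistogram(
        K=K, counts={int(m_): int(c) for m_, c in enumerate(hist) if m_ >= 1 and c > 0}
    )


def _error_trough(dense: np.ndarray, start: int) -> int | None:
    """First local minimum of counts vs multiplicity, scanning upward.

    Returns the smallest multiplicity of the minimum's plateau, or None if
    counts never rise again (no coverage peak).
    """
    top = dense.size - 1
    for m in range(max(start, 1), top):
        if dense[m + 1] > dense[m]:
            while m > 1 and dense[m - 1] == dense[m]:
                m -= 1
            return m
    return None


def find_coverage_peak(hist: KmerHistogram, min_multiplicity_search: int = 1) -> int:
    """Locate the homozygous-coverage peak of a multiplicity histogram.

    Scans upward from ``min_multiplicity_search`` for the error trough (the
    first local minimum separating the error spike from true coverage), then
    returns the multiplicity with the maximum count beyond it.
    """
    if not hist.counts:
        raise ValueError("empty histogram")
    dense = hist.dense()
    trough = _error_trough(dense, min_multiplicity_search)
    if trough is None:
        raise ValueError("no coverage peak; data may be error-dominated")
    beyond = dense[trough + 1 :]
    return int(trough + 1 + np.argmax(beyond))


def estimate_size(
    hist: KmerHistogram,
    L: float,
    exclude_error_peak: bool = True,
) -> GenomeSizeEstimate:
    """Estimate genome size from a k-mer histogram and mean read length.

    ``c_kmer`` is refined from the integer histogram mode to the
    count-weighted mean multiplicity in a window around the mode, which is
    stable when the underlying coverage falls between two integers. With
    ``exclude_error_peak`` the observations below the error trough are left
    out of ``n_kmer``.
    """
    if L <= hist.K:
        raise ValueError("mean read length L must exceed K")
    mode = find_coverage_peak(hist)
    dense = hist.dense()
    half = max(2, round(0.15 * mode))
    lo, hi = max(1, mode - half), min(dense.size - 1, mode + half)
    window_m = np.arange(lo, hi + 1)
    window_c = dense[lo : hi + 1]
    c_kmer = float((window_m * window_c).sum() / window_c.sum())
    if exclude_error_peak:
        trough = _error_trough(dense, 1)
        ms = np.arange(dense.size)
        used = (ms > trough) if trough is not None else (ms >= 1)
        n_kmer = int((ms[used] * dense[used]).sum())
    else:
        n_kmer = hist.n_kmer
    G = int(round(n_kmer / c_kmer))
    c_base = c_kmer * L / (L - hist.K + 1)
    n_base = n_kmer * L / (L - hist.K + 1)
    return GenomeSizeEstimate(
        G=G, c_kmer=c_kmer, c_base=c_base, L=float(L), K=hist.K,
        n_base=n_base, n_kmer=n_kmer,
    )
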