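"""k-mer abundance spectra: counting, log-binning, Zipf ranks.

The central object is the abundance spectrum n_k(s): for a fixed k-mer
length k, the number of *distinct* k-mers that occur exactly s times in a
sequence set.  Counting is forward-strand, overlapping windows; windows
containing non-ACGT characters are skipped.

Two counting paths produce identical abundances:

* :func:`count_kmers` -- an explicit dictionary counter over string
  windows; the reference implementation, also handles ragged/ambiguous
  input.
* :func:`kmer_abundances` -- a 2-bit-packed numpy path for large
  equal-length sequence matrices (each k-mer maps to ceil(k/32) uint64
  words, so the packing is exact, not a hash), used by the inference
  pipeline where only the multiset of abundances matters.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

__all__ = [
    "AbundanceSpectrum",
    "BinnedSpectrum",
    "count_kmers",
    "kmer_abundances",
    "spectrum_from_counts",
    "log_bin",
    "zipf_ranks",
]

_INVALID = re.compile("[^ACGT]")


def count_kmers(sequences, k: int) -> dict[str, int]:
    """Count every length-k window of every sequence (forward strand).

    Windows containing characters outside {A,C,G,T} are skipped.  Input is
    uppercased.  Returns an empty mapping when no sequence is long enough.
    """
    if k < 1:
        raise DomainError(f"k must be >= 1, got {k}")
    counts: Counter[str] = Counter()
    for seq in sequences:
        s = str(seq).upper()
        # split on ambiguity characters so offending windows never form
        for run in _INVALID.split(s):
            if len(run) >= k:
                counts.update(run[i : i + k] for i in range(len(run) - k + 1))
    return dict(counts)


def _rolling_pack(matrix: np.ndarray, m: int) -> np.ndarray:
    """2-bit-pack every m-mer (m <= 32) of each row into one uint64.

    Returns an (n, L - m + 1) uint64 array built by a rolling shift along
    the sequence axis, so the cost is O(n * L) regardless of m.
    """
    n, L = matrix.shape
    base = matrix.astype(np.uint64)
    mask = np.uint64((1 << (2 * m)) - 1) if m < 32 else np.uint64(0xFFFFFFFFFFFFFFFF)
    v = np.zeros(n, dtype=np.uint64)
    out = np.empty((n, L - m + 1), dtype=np.uint64)
    two = np.uint64(2)
    for j in range(L):
        v = ((v << two) | base[:, j]) & mask
        if j >= m - 1:
            out[:, j - m + 1] = v
    return out


def _pack_windows(matrix: np.ndarray, k: int) -> np.ndarray:
    """2-bit-pack all k-windows of an (n, L) base matrix into uint64 words.

    Returns an (n_windows, ceil(k/32)) uint64 array; two windows are equal
    iff their rows are equal (exact encoding, no hashing).  Word c of the
    window starting at p packs bases p + 32c .. p + min(k, 32(c+1)) - 1.
    """
    n, L = matrix.shape
    W = L - k + 1
    n_chunks = -(-k // 32)
    packed = np.empty((n * W, n_chunks), dtype=np.uint64)
    for c in range(n_chunks):
        m = min(k, 32 * (c + 1)) - 32 * c
        rolled = _rolling_pack(matrix[:, 32 * c :], m)
        packed[:, c] = rolled[:, :W].reshape(-1)
    return packed


def kmer_abundances(matrix: np.ndarray, k: int) -> np.ndarray:
    """Abundances of all distinct k-mers in an (n, L) uint8 base matrix.

    Returns the unordered array of occurrence counts (one entry per
    distinct k-mer).  Exact: equivalent to ``count_kmers`` on the decoded
    sequences.
    """
    if k < 1:
        raise DomainError(f"k must be >= 1, got {k}")
    n, L = matrix.shape
    if L < k or n == 0:
        return np.zeros(0, dtype=np.int64)
    packed = _pack_windows(matrix, k)
    if packed.shape[1] == 1:
        _, counts = np.unique(packed[:, 0], return_counts=True)
        return counts.astype(np.int64)
    # multi-word k-mers: lexicographic row sort via chained stable argsorts
    # (radix sort for integer keys), then run-length encode equal rows
    order = np.argsort(packed[:, -1], kind="stable")
    for j in range(packed.shape[1] - 2, -1, -1):
        order = order[np.argsort(packed[order, j], kind="stable")]
    change = np.zeros(len(packed), dtype=bool)
    change[0] = True
    for j in range(packed.shape[1]):
        col = packed[order, j]
        change[1:] |= col[1:] != col[:-1]
    starts = np.flatnonzero(change)
    counts = np.diff(np.append(starts, len(packed)))
    return counts.astype(np.int64)


@dataclass
class AbundanceSpectrum:
    """n_k(s): distinct-k-mer count per abundance s, for one k.

    Invariant: sum_s s * n_k(s) == total_kmers (every window is some
    k-mer's occurrence).
    """

    k: int
    entries: dict[int, int]
    total_kmers: int = field(default=0)

    def __post_init__(self) -> None:
        occ = sum(s * n for s, n in self.entries.items())
        if self.total_kmers == 0:
            self.total_kmers = occ
        elif occ != self.total_kmers:
            raise DomainError(
                f"spectrum violates conservation: sum s*n = {occ}, "
                f"total_kmers = {self.total_kmers}"
            )

    @property
    def abundances(self) -> np.ndarray:
        """Sorted abundance values s with n_k(s) >= 1."""
        return np.array(sorted(self.entries), dtype=np.int64)

    def tail_sample(self, s_min: int = 3) -> np.ndarray:
        """One observation per distinct k-mer with abundance >= s_min."""
        return np.repeat(
            [s for s in sorted(self.entries) if s >= s_min],
            [self.entries[s] for s in sorted(self.entries) if s >= s_min],
        ).astype(np.int64)


def spectrum_from_counts(counts, k: int) -> AbundanceSpectrum:
    """Build the abundance spectrum from a k-mer -> count mapping or from a
    plain array of abundances (the output of :func:`kmer_abundances`)."""
    if isinstance(counts, dict):
        values = np.fromiter(counts.values(), dtype=np.int64, count=len(counts))
    else:
        values = np.asarray(counts, dtype=np.int64)
    if values.size == 0:
        return AbundanceSpectrum(k=k, entries={})
    s, n = np.unique(values, return_counts=True)
    return AbundanceSpectrum(k=k, entries={int(a): int(b) for a, b in zip(s, n)})


@dataclass
class BinnedSpectrum:
    """Log-binned abundance spectrum.

    Abundances s <= threshold keep unit bins; above the threshold, bin
    edges follow a geometric progression threshold * ratio^j, snapped to
    the half-open integer ranges [lo, hi).  ``mass`` is the summed n_k(s)
    in a bin and ``density`` mass per integer abundance (mass / (hi - lo)),
    which is the quantity whose log-log slope estimates -alpha.  Bin
    centers are geometric means sqrt(lo * hi).  Total mass is conserved
    exactly.
    """

    k: int
    lo: np.ndarray
    hi: np.ndarray
    mass: np.ndarray
    density: np.ndarray
    threshold: int
    ratio: float

    @property
    def centers(self) -> np.ndarray:
        return np.sqrt(self.lo * self.hi)

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())


def log_bin(
    spectrum: AbundanceSpectrum, threshold: int = 7, ratio: float = 1.1885
) -> BinnedSpectrum:
    """Logarithmically bin a spectrum above ``threshold`` (default edge
    ratio 1.1885); unit bins below.  Empty bins are dropped."""
    if ratio <= 1:
        raise DomainError(f"ratio must be > 1, got {ratio}")
    if threshold < 1:
        raise DomainError(f"threshold must be >= 1, got {threshold}")
    lo_list: list[int] = []
    hi_list: list[int] = []
    mass_list: list[int] = []

    items = sorted(spectrum.entries.items())
    s_max = items[-1][0] if items else 0

    # unit bins for occupied s <= threshold
    for s, n in items:
        if s > threshold:
            break
        lo_list.append(s)
        hi_list.append(s + 1)
        mass_list.append(n)

    # geometric bins above the threshold, snapped to integer boundaries
    if s_max > threshold:
        edges = [threshold + 1]
        e = float(threshold)
        while e <= s_max:
            e *= ratio
            b = max(int(np.ceil(e)), edges[-1] + 1)
            edges.append(b)
            if b > s_max:
                break
        tail = [(s, n) for s, n in items if s > threshold]
        idx = 0
        for blo, bhi in zip(edges[:-1], edges[1:]):
            m = 0
            while idx < len(tail) and tail[idx][0] < bhi:
                m += tail[idx][1]
                idx += 1
            if m > 0:
                lo_list.append(blo)
                hi_list.append(bhi)
                mass_list.append(m)

    lo = np.array(lo_list, dtype=np.float64)
    hi = np.array(hi_list, dtype=np.float64)
    mass = np.array(mass_list, dtype=np.float64)
    width = hi - lo
    density = np.divide(mass, width, out=np.zeros_like(mass), where=width > 0)
    return BinnedSpectrum(
        k=spectrum.k,
        lo=lo,
        hi=hi,
        mass=mass,
        density=density,
        threshold=threshold,
        ratio=ratio,
    )


def zipf_ranks(counts) -> list[tuple[int, int]]:
    """Abundances sorted descending with ranks 1..n (Zipf view).

    Accepts a k-mer -> count mapping or a bare abundance array; returns an
    empty list for empty input.
    """
    if isinstance(counts, dict):
        values = sorted(counts.values(), reverse=True)
    else:
        values = sorted((int(v) for v in np.asarray(counts).ravel()), reverse=True)
    return [(r + 1, v) for r, v in enumerate(values)]
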