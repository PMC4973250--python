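"""Synthetic inputs with the statistical structure the model assumes.

* :func:`make_ancestral` -- a synthetic ancestral element with an *exact*
  CpG dinucleotide count, standing in for an AluSx-like consensus
  (defaults L = 300, 24 CpGs; no real consensus is bundled -- users supply
  one via FASTA if they want it).
* :func:`sample_discrete_powerlaw` -- exact i.i.d. draws from the discrete
  power law P(s) = s^{-alpha} / zeta(alpha, s_min), s >= s_min, via
  inverse-CDF on the Hurwitz-zeta-normalised mass function; used to
  calibrate the Hill estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .errors import DomainError

__all__ = ["AncestorSpec", "make_ancestral", "sample_discrete_powerlaw"]


@dataclass(frozen=True)
class AncestorSpec:
    """Recipe for a synthetic ancestor: length, exact CpG count, GC content.

    The default GC fraction 0.56 matches the GC-richness typical of Alu
    consensus sequences.
    """

    L: int = 300
    n_cpg: int = 24
    gc_content: float = 0.56
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise DomainError(f"L must be >= 1, got {self.L}")
        if not 0 <= 2 * self.n_cpg <= self.L:
            raise DomainError(
                f"infeasible: need 0 <= 2*n_cpg <= L, got n_cpg={self.n_cpg}, L={self.L}"
            )
        if not 0.0 <= self.gc_content <= 1.0:
            raise DomainError(f"gc_content must be in [0, 1], got {self.gc_content}")


def make_ancestral(spec: AncestorSpec) -> str:
    """Deterministic (per seed) sequence of length L with exactly n_cpg "CG"s.

    Construction: place n_cpg non-overlapping CG blocks at uniformly random
    positions, then fill the free positions left to right, resampling any
    letter that would create an additional CG with a fixed or already
    placed neighbour (A and T are always admissible, so filling never dead
    ends).  A final scan asserts the exact count.
    """
    rng = np.random.default_rng(spec.seed)
    L, n = spec.L, spec.n_cpg
    seq = np.full(L, ord("?"), dtype=np.uint8)

    if n > 0:
        # choose n non-overlapping block starts: pick n of the L - 2n + 1
        # gap slots and spread them by the block width
        slots = np.sort(rng.choice(L - 2 * n + 1, size=n, replace=False))
        starts = slots + 2 * np.arange(n)
        for s in starts:
            seq[s] = ord("C")
            seq[s + 1] = ord("G")

    gc = spec.gc_content
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    letters = np.frombuffer(b"ACGT", dtype=np.uint8)
    free = np.flatnonzero(seq == ord("?"))
    for p in free:
        while True:
            b = letters[rng.choice(4, p=base_p)]
            left_makes_cg = p > 0 and seq[p - 1] == ord("C") and b == ord("G")
            right_makes_cg = p + 1 < L and b == ord("C") and seq[p + 1] == ord("G")
            if not (left_makes_cg or right_makes_cg):
                seq[p] = b
                break

    out = seq.tobytes().decode("ascii")
    assert out.count("CG") == n, "CpG placement violated its exact-count contract"
    return out


def sample_discrete_powerlaw(
    alpha: float, s_min: int, n: int, seed: int, _table_cap: int = 100_000
) -> np.ndarray:
    """n i.i.d. draws from P(s) = s^{-alpha} / zeta(alpha, s_min), s >= s_min.

    Inverse-CDF sampling: the CDF is tabulated exactly up to ``_table_cap``;
    the (rare) draws beyond the table are resolved by bisection on the
    Hurwitz-zeta survival function, so the sampler is exact over the whole
    support.
    """
    if alpha <= 1:
        raise DomainError(f"alpha must be > 1 (normalisable), got {alpha}")
    if s_min < 1:
        raise DomainError(f"s_min must be >= 1, got {s_min}")
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")

    rng = np.random.default_rng(seed)
    z = float(special.zeta(alpha, s_min))
    support = np.arange(s_min, _table_cap + 1, dtype=np.float64)
    pmf = support ** (-alpha) / z
    cdf = np.cumsum(pmf)

    u = rng.random(n)
    idx = np.searchsorted(cdf, u, side="left")
    out = s_min + idx.astype(np.int64)

    # draws past the table: solve zeta(alpha, s+1) <= (1-u) * z by bisection
    beyond = np.flatnonzero(idx >= len(cdf))
    for i in beyond:
        target = (1.0 - u[i]) * z
        lo = _table_cap + 1
        hi = 2 * lo
        while special.zeta(alpha, hi + 1) > target:
            lo, hi = hi, 2 * hi
        while lo < hi:
            mid = (lo + hi) // 2
            if special.zeta(alpha, mid + 1) <= target:
                hi = mid
            else:
                lo = mid + 1
        out[i] = lo
    return out
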