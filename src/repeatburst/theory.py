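"""Closed-form results for the burst-and-silence model of repeat expansion.

The model: a single active element of length ``L`` appears at time 0.  During
a burst of duration ``T1`` every *active* element duplicates at rate ``gamma``;
each new copy is active with probability ``delta`` and permanently silent
otherwise.  After the burst all elements are silent for a further time ``T2``
and only accumulate point mutations.  Nucleotides mutate at rate ``mu0``
(the unit of time is ``1/mu0``) except CpG dinucleotides, whose two positions
mutate ``cpg_factor`` (default 6) times faster through deamination.

This module holds the analytic consequences of that process:

* ``expected_copies`` -- the mean family size N(t) = 1 + (e^{dg*t} - 1)/delta,
  where dg = delta*gamma is the effective duplication rate.  The "+1" is the
  founder; the formula is the exact mean of the branching process, reducing to
  e^{gamma*t} for delta = 1 and to 1 + gamma*t in the master-gene limit
  delta -> 0.
* ``effective_mu`` -- the CpG-weighted average per-nucleotide mutation rate.
* ``survival_prob`` -- probability p_k = exp(-mu*k*T2) that a k-mer survives
  the silent phase unmutated.
* ``alpha_of_k`` -- the exponent of the power-law tail of the k-mer abundance
  distribution, alpha(k) = (2 - mu*k/dg) / (1 - mu*k/dg), valid while
  mu*k < dg.  It equals 2 in the mutation-free (small-k) limit and grows
  with k.
* ``tail_density`` -- the expected number n_k(s) of distinct k-mers with
  abundance s in the tail,
  n_k(s) = (alpha - 2) * N * (L - k + 1) * p_k^{alpha-1} * s^{-alpha}.

All rates are in units of mu0 and times in units of 1/mu0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

from .errors import DomainError, NoPowerLawTailError

__all__ = [
    "ModelParams",
    "EffectiveRates",
    "TailPrediction",
    "effective_mu",
    "expected_copies",
    "alpha_of_k",
    "survival_prob",
    "tail_density",
]


@dataclass(frozen=True)
class ModelParams:
    """Rate and time constants of the expansion model.

    Parameters
    ----------
    gamma : float
        Duplication rate per active element, in units of mu0.
    delta : float
        Probability that a new copy is active, in [0, 1].  delta = 1 is the
        transposon model (every copy duplicates), delta -> 0 the master-gene
        model (one active source).
    mu0 : float
        Background per-nucleotide mutation rate; the time unit.  Default 1.
    cpg_factor : float
        Total mutation-rate multiplier at CpG positions.  Default 6.
    T1 : float
        Burst duration, units 1/mu0.
    T2 : float
        Silent-phase duration, units 1/mu0.
    L : int
        Element length in bp.  Default 300 (Alu-like).
    n_cpg : int
        Number of CpG dinucleotides in the ancestral element.  Default 24
        (the count in an AluSx-like consensus).
    """

    gamma: float
    delta: float
    mu0: float = 1.0
    cpg_factor: float = 6.0
    T1: float = 0.0
    T2: float = 0.0
    L: int = 300
    n_cpg: int = 24

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise DomainError(f"gamma must be > 0, got {self.gamma}")
        if not 0.0 <= self.delta <= 1.0:
            raise DomainError(f"delta must be in [0, 1], got {self.delta}")
        if self.mu0 <= 0:
            raise DomainError(f"mu0 must be > 0, got {self.mu0}")
        if self.cpg_factor < 1:
            raise DomainError(f"cpg_factor must be >= 1, got {self.cpg_factor}")
        if self.T1 < 0 or self.T2 < 0:
            raise DomainError("T1 and T2 must be >= 0")
        if self.L < 1:
            raise DomainError(f"L must be >= 1, got {self.L}")
        if not 0 <= 2 * self.n_cpg <= self.L:
            raise DomainError(
                f"need 0 <= 2*n_cpg <= L, got n_cpg={self.n_cpg}, L={self.L}"
            )

    @property
    def delta_gamma(self) -> float:
        """Effective duplication rate delta*gamma, units mu0."""
        return self.delta * self.gamma

    @property
    def mu(self) -> float:
        """Effective (CpG-weighted) per-nucleotide mutation rate, units mu0."""
        return effective_mu(self.L, self.n_cpg, self.cpg_factor) * self.mu0

    def rates(self) -> "EffectiveRates":
        return EffectiveRates(mu=self.mu, delta_gamma=self.delta_gamma)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class EffectiveRates:
    """Effective rates (mu, delta*gamma) and their dimensionless ratio."""

    mu: float
    delta_gamma: float
    ratio: float = field(init=False)

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise DomainError(f"mu must be >= 0, got {self.mu}")
        if self.delta_gamma <= 0:
            raise DomainError(f"delta_gamma must be > 0, got {self.delta_gamma}")
        object.__setattr__(self, "ratio", self.mu / self.delta_gamma)


@dataclass(frozen=True)
class TailPrediction:
    """Analytic tail prediction for one k: exponent, survival prob, family size."""

    k: int
    alpha: float
    p_k: float
    N: float


def effective_mu(L: int, n_cpg: int, cpg_factor: float = 6.0) -> float:
    """CpG-weighted average per-nucleotide mutation rate, in units of mu0.

    ``2*n_cpg`` positions mutate at ``cpg_factor`` times the background rate,
    the remaining ``L - 2*n_cpg`` at the background rate:

        mu = ((L - 2*n_cpg) + 2*n_cpg*cpg_factor) / L

    For an Alu-like element (L=300, 24 CpGs, factor 6) this gives 1.8.
    """
    if L < 1:
        raise DomainError(f"L must be >= 1, got {L}")
    if n_cpg < 0 or 2 * n_cpg > L:
        raise DomainError(f"need 0 <= 2*n_cpg <= L, got n_cpg={n_cpg}, L={L}")
    return ((L - 2 * n_cpg) + 2 * n_cpg * cpg_factor) / L


def expected_copies(t: float, params: ModelParams) -> float:
    """Mean number of elements at time t <= T1 under the branching model.

    N(t) = 1 + (exp(delta*gamma*t) - 1) / delta, the exact mean of the
    process (founder included).  Continuous at delta = 0, where it becomes
    1 + gamma*t (only the founder ever duplicates).
    """
    if t < 0:
        raise DomainError(f"t must be >= 0, got {t}")
    if params.delta == 0.0:
        return 1.0 + params.gamma * t
    return 1.0 + math.expm1(params.delta_gamma * t) / params.delta


def alpha_of_k(k: float, rates: EffectiveRates) -> float:
    """Power-law exponent of the k-mer abundance tail.

        alpha(k) = (2 - mu*k/dg) / (1 - mu*k/dg),  dg = delta*gamma

    equivalently 2 + mu*k/(dg - mu*k).  The tail exists only while
    mu*k < dg; alpha -> 2 as k -> 0 and diverges as mu*k -> dg.
    """
    if k < 0:
        raise DomainError(f"k must be >= 0, got {k}")
    x = rates.mu * k / rates.delta_gamma
    if x >= 1.0:
        raise NoPowerLawTailError(
            f"no power-law tail: mu*k = {rates.mu * k:g} >= "
            f"delta*gamma = {rates.delta_gamma:g}"
        )
    return (2.0 - x) / (1.0 - x)


def survival_prob(k: int, mu: float, T2: float) -> float:
    """Probability exp(-mu*k*T2) that a k-mer stays unmutated for a time T2."""
    if k < 1:
        raise DomainError(f"k must be >= 1, got {k}")
    if mu < 0 or T2 < 0:
        raise DomainError("mu and T2 must be >= 0")
    return math.exp(-mu * k * T2)


def tail_density(s: float, k: int, params: ModelParams) -> float:
    """Expected number n_k(s) of distinct k-mers with abundance s (tail regime).

        n_k(s) = (alpha - 2) * N * (L - k + 1) * p_k^{alpha - 1} * s^{-alpha}

    with N the mean family size at the end of the burst, p_k the silent-phase
    survival probability and alpha = alpha_of_k(k).  The prefactor
    alpha - 2 = mu*k/(dg - mu*k) is the rate at which mutation seeds new
    k-mer clones relative to their net growth; it vanishes at mu = 0, where
    no mutant clones (hence no tail) exist.
    """
    if s < 1:
        raise DomainError(f"s must be >= 1, got {s}")
    if not 1 <= k <= params.L:
        raise DomainError(f"need 1 <= k <= L, got k={k}, L={params.L}")
    rates = params.rates()
    alpha = alpha_of_k(k, rates)  # raises NoPowerLawTailError when mu*k >= dg
    N = expected_copies(params.T1, params)
    p_k = survival_prob(k, rates.mu, params.T2)
    return (alpha - 2.0) * N * (params.L - k + 1) * p_k ** (alpha - 1.0) * s ** (-alpha)


def predict_tail(k: int, params: ModelParams) -> TailPrediction:
    """Bundle the per-k analytic quantities used by the fitting pipeline."""
    rates = params.rates()
    return TailPrediction(
        k=k,
        alpha=alpha_of_k(k, rates),
        p_k=survival_prob(k, rates.mu, params.T2),
        N=expected_copies(params.T1, params),
    )
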