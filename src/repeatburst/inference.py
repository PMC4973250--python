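"""Parameter estimation from repeat-element sequences.

The pipeline mirrors how the expansion model is confronted with data:

1. ``estimate_N`` -- family size from total k-mer occurrences averaged over
   a k grid (default 5..90), N = mean_k [ total_k / (L - k + 1) ].
2. ``hill_exponent`` / ``exponent_curve`` -- per-k tail exponents of the
   abundance spectra via the discrete Hill maximum-likelihood estimator
   over abundances s >= s_min (default 3), with the -1/2 continuity shift:

       alpha_hat = 1 + n * [ sum_i ln( s_i / (s_min - 1/2) ) ]^{-1}

   one observation per *distinct* k-mer.
3. ``fit_ratio`` -- nonlinear least squares of the analytic exponent
   alpha(k) = (2 - r*k)/(1 - r*k) to the curve over 35 <= k <= 75, with the
   single free parameter r = mu/(delta*gamma).
4. ``estimate_T1`` -- invert the mean-growth law N(T1) = N for the burst
   duration.
5. ``fit_T2`` -- grid search: simulate the model (delta = 1) at each
   candidate T2 and score the log-density mean-squared difference between
   log-binned simulated and reference spectra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import DomainError, EstimationError
from .spectrum import (
    AbundanceSpectrum,
    BinnedSpectrum,
    count_kmers,
    kmer_abundances,
    log_bin,
    spectrum_from_counts,
)
from .theory import ModelParams

__all__ = [
    "ExponentCurve",
    "FitResult",
    "T2Profile",
    "hill_exponent",
    "exponent_curve",
    "fit_ratio",
    "estimate_N",
    "estimate_T1",
    "fit_T2",
]


def hill_exponent(abundances, s_min: int = 3) -> float:
    """Discrete Hill ML estimate of the power-law tail exponent.

    ``abundances`` is the sample of distinct-k-mer abundances; only values
    >= s_min enter.  Requires at least two tail observations.
    """
    s = np.asarray(abundances, dtype=np.float64)
    tail = s[s >= s_min]
    if tail.size < 2:
        raise EstimationError(
            f"need >= 2 abundances >= s_min={s_min}, got {tail.size}"
        )
    log_sum = float(np.log(tail / (s_min - 0.5)).sum())
    if log_sum <= 0:
        raise EstimationError("degenerate tail sample (all at s_min boundary?)")
    return 1.0 + tail.size / log_sum


def hill_stderr(alpha_hat: float, n_tail: int) -> float:
    """Asymptotic standard error of the Hill estimate, (alpha-1)/sqrt(n)."""
    return (alpha_hat - 1.0) / math.sqrt(n_tail)


@dataclass
class ExponentCurve:
    """Per-k Hill estimates alpha_hat(k) with tail sample sizes."""

    k: np.ndarray
    alpha: np.ndarray
    n_tail: np.ndarray
    s_min: int = 3

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=np.int64)
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        self.n_tail = np.asarray(self.n_tail, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.k)

    @property
    def stderr(self) -> np.ndarray:
        return (self.alpha - 1.0) / np.sqrt(self.n_tail)

    def window(self, k_lo: int, k_hi: int) -> "ExponentCurve":
        m = (self.k >= k_lo) & (self.k <= k_hi)
        return ExponentCurve(self.k[m], self.alpha[m], self.n_tail[m], self.s_min)


def _abundance_arrays(elements, k: int) -> np.ndarray:
    """Distinct-k-mer abundances from an ElementSet, matrix, or sequences."""
    matrix = getattr(elements, "matrix", None)
    if matrix is None and isinstance(elements, np.ndarray) and elements.ndim == 2:
        matrix = elements
    if matrix is not None:
        return kmer_abundances(matrix, k)
    counts = count_kmers(elements, k)
    return np.fromiter(counts.values(), dtype=np.int64, count=len(counts))


def exponent_curve(elements, k_values, s_min: int = 3) -> ExponentCurve:
    """Hill exponent per k over a sequence set; k with <2 tail points are
    skipped.  Raises :class:`EstimationError` if every k is skipped."""
    ks, alphas, ns = [], [], []
    for k in k_values:
        ab = _abundance_arrays(elements, int(k))
        tail = ab[ab >= s_min]
        if tail.size < 2:
            continue
        try:
            a = hill_exponent(tail, s_min=s_min)
        except EstimationError:
            continue
        ks.append(int(k))
        alphas.append(a)
        ns.append(int(tail.size))
    if not ks:
        raise EstimationError(
            f"no k in {list(k_values)} had >= 2 abundances >= {s_min}"
        )
    return ExponentCurve(np.array(ks), np.array(alphas), np.array(ns), s_min)


@dataclass
class FitResult:
    """Single-parameter fit of the analytic exponent curve.

    ratio_hat estimates r = mu/(delta*gamma); residual_norm is the sum of
    squared residuals over the n_points fitted k values.
    """

    ratio_hat: float
    k_range: tuple[int, int]
    residual_norm: float
    n_points: int

    def __post_init__(self) -> None:
        if self.ratio_hat <= 0:
            raise EstimationError(f"ratio_hat must be > 0, got {self.ratio_hat}")
        if self.n_points < 2:
            raise EstimationError(f"need >= 2 fitted points, got {self.n_points}")


def _alpha_model(k: np.ndarray, r: float) -> np.ndarray:
    x = r * k
    return (2.0 - x) / (1.0 - x)


def fit_ratio(curve: ExponentCurve, k_lo: int = 35, k_hi: int = 75) -> FitResult:
    """Least-squares fit of alpha(k) = (2 - r*k)/(1 - r*k) with r free.

    The initial guess inverts the curve point-wise (r = (a-2)/((a-1) k));
    the solver is bounded so r*k stays below 1 on the fit window.
    """
    win = curve.window(k_lo, k_hi)
    if len(win) < 2:
        raise EstimationError(
            f"need >= 2 curve points in [{k_lo}, {k_hi}], have {len(win)}"
        )
    k = win.k.astype(np.float64)
    a = win.alpha
    r_max = (1.0 - 1e-9) / k.max()
    with np.errstate(divide="ignore", invalid="ignore"):
        r_pt = (a - 2.0) / ((a - 1.0) * k)
    r_pt = r_pt[np.isfinite(r_pt) & (r_pt > 0)]
    r0 = float(np.clip(np.median(r_pt), 1e-9, 0.9 * r_max)) if r_pt.size else 0.5 * r_max

    res = optimize.least_squares(
        lambda r: _alpha_model(k, r[0]) - a,
        x0=[r0],
        bounds=([1e-12], [r_max]),
        method="trf",
    )
    if not res.success:
        raise EstimationError(f"exponent-curve fit did not converge: {res.message}")
    return FitResult(
        ratio_hat=float(res.x[0]),
        k_range=(k_lo, k_hi),
        residual_norm=float(2.0 * res.cost),
        n_points=len(win),
    )


def _total_windows(elements, k: int) -> int:
    """Total number of counted k-mer occurrences in the sequence set."""
    matrix = getattr(elements, "matrix", None)
    if matrix is None and isinstance(elements, np.ndarray) and elements.ndim == 2:
        matrix = elements
    if matrix is not None:
        n, L = matrix.shape
        return n * max(0, L - k + 1)
    import re

    total = 0
    for seq in elements:
        for run in re.split("[^ACGT]", str(seq).upper()):
            total += max(0, len(run) - k + 1)
    return total


def estimate_N(elements, k_values=None, L: int = 300) -> float:
    """Element-count estimator: mean over k of total_k / (L - k + 1).

    Exact (equal to the number of sequences, for every k subset) when all
    sequences have length L; for mixed lengths it averages the per-k
    length-weighted counts.
    """
    if k_values is None:
        k_values = range(5, 91)
    k_values = list(k_values)
    if not k_values:
        raise DomainError("k_values is empty")
    if L <= max(k_values):
        raise DomainError(f"L={L} must exceed max k={max(k_values)}")
    vals = [_total_windows(elements, int(k)) / (L - int(k) + 1) for k in k_values]
    return float(np.mean(vals))


def estimate_T1(N: float, params: ModelParams) -> float:
    """Invert the mean-growth law for the burst duration.

    Solves 1 + (e^{delta*gamma*t} - 1)/delta = N in closed form:
    t = ln(delta*(N - 1) + 1) / (delta*gamma), or (N - 1)/gamma at delta=0.
    """
    if N < 1:
        raise DomainError(f"N must be >= 1, got {N}")
    if params.delta == 0.0:
        return (N - 1.0) / params.gamma
    return math.log(params.delta * (N - 1.0) + 1.0) / params.delta_gamma


@dataclass
class T2Profile:
    """Grid-search result for the silent-phase duration."""

    t2_grid: np.ndarray
    distances: np.ndarray
    best_t2: float


def spectra_distance(
    ref: dict[int, BinnedSpectrum], sim: dict[int, BinnedSpectrum]
) -> float:
    """Mean squared difference of log10 densities over shared bins, summed
    over the k values present in both collections."""
    total = 0.0
    shared_k = sorted(set(ref) & set(sim))
    if not shared_k:
        raise EstimationError("no shared k between reference and simulated spectra")
    for k in shared_k:
        r, s = ref[k], sim[k]
        r_map = {(lo, hi): d for lo, hi, d in zip(r.lo, r.hi, r.density)}
        s_map = {(lo, hi): d for lo, hi, d in zip(s.lo, s.hi, s.density)}
        shared = [b for b in r_map if b in s_map and r_map[b] > 0 and s_map[b] > 0]
        if not shared:
            continue
        diffs = [
            (math.log10(r_map[b]) - math.log10(s_map[b])) ** 2 for b in shared
        ]
        total += float(np.mean(diffs))
    return total


def fit_T2(
    reference_spectra: dict[int, AbundanceSpectrum],
    params_without_T2: ModelParams,
    T2_grid,
    seed: int,
    target_n: int,
    ancestor: str | None = None,
    n_seeds: int = 3,
    s_min_bin_threshold: int = 7,
    bin_ratio: float = 1.1885,
) -> T2Profile:
    """Grid search for T2: simulate (delta = 1) at each grid value and score
    the binned-spectrum distance to the reference, averaged over seeds.

    ``reference_spectra`` maps k to :class:`AbundanceSpectrum`.  The same
    binning (threshold, ratio) is applied to both sides.
    """
    from .model import simulate_family  # deferred: model composes this module
    from .synthetic import AncestorSpec, make_ancestral

    grid = np.asarray(list(T2_grid), dtype=np.float64)
    if grid.size == 0:
        raise DomainError("T2 grid is empty")
    base = params_without_T2
    if ancestor is None:
        ancestor = make_ancestral(
            AncestorSpec(L=base.L, n_cpg=base.n_cpg, seed=seed)
        )
    k_values = sorted(reference_spectra)
    ref_binned = {
        k: log_bin(sp, threshold=s_min_bin_threshold, ratio=bin_ratio)
        for k, sp in reference_spectra.items()
    }
    rng = np.random.default_rng(seed)
    sim_seeds = rng.integers(0, 2**31 - 1, size=(grid.size, n_seeds))

    distances = np.empty(grid.size)
    for i, t2 in enumerate(grid):
        params = ModelParams(
            gamma=base.delta_gamma,  # delta = 1 keeps delta*gamma fixed
            delta=1.0,
            mu0=base.mu0,
            cpg_factor=base.cpg_factor,
            T1=base.T1,
            T2=float(t2),
            L=base.L,
            n_cpg=base.n_cpg,
        )
        d_seeds = []
        for j in range(n_seeds):
            elements = simulate_family(
                params, target_n=target_n, seed=int(sim_seeds[i, j]), ancestor=ancestor
            )
            sim_binned = {
                k: log_bin(
                    spectrum_from_counts(kmer_abundances(elements.matrix, k), k),
                    threshold=s_min_bin_threshold,
                    ratio=bin_ratio,
                )
                for k in k_values
            }
            d_seeds.append(spectra_distance(ref_binned, sim_binned))
        distances[i] = float(np.mean(d_seeds))
    best = grid[int(np.argmin(distances))]
    return T2Profile(t2_grid=grid, distances=distances, best_t2=float(best))
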