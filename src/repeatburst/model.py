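"""Model / Results interface and the end-to-end pipeline.

:class:`RepeatFamilyModel` wraps a set of repeat-element sequences (real or
simulated) and, on ``fit()``, runs the full inference chain -- family-size
estimate, per-k Hill exponents, the single-parameter fit of the analytic
exponent curve, and the burst-duration inversion -- returning a
:class:`RepeatFamilyResults` with estimates, standard errors and a
``summary()`` table.  Simulation (``simulate_family``) and the one-command
``run_pipeline`` hang off the same machinery.
"""

from __future__ import annotations

import json
import math
import time as _time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import fileio
from .errors import DomainError, InputError
from .inference import (
    ExponentCurve,
    FitResult,
    T2Profile,
    estimate_N,
    estimate_T1,
    exponent_curve,
    fit_T2,
    fit_ratio,
)
from .seqevo import ElementSet, encode, evolve_sequences
from .spectrum import kmer_abundances, log_bin, spectrum_from_counts
from .synthetic import AncestorSpec, make_ancestral
from .theory import ModelParams, effective_mu
from .treesim import BranchingTree, SimConfig, simulate_burst

__all__ = [
    "RepeatFamilyModel",
    "RepeatFamilyResults",
    "PipelineConfig",
    "simulate_family",
    "simulate_tree_and_family",
    "run_pipeline",
]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def simulate_tree_and_family(
    params: ModelParams,
    target_n: int,
    seed: int,
    ancestor: str | None = None,
) -> tuple[BranchingTree, ElementSet]:
    """Simulate one burst genealogy and evolve sequences along it.

    The master seed is split into independent streams for the ancestor (if
    not supplied), the tree and the sequences, so runs are reproducible.
    """
    seed_anc, seed_tree, seed_seq = _spawn_seeds(seed, 3)
    if ancestor is None:
        ancestor = make_ancestral(
            AncestorSpec(L=params.L, n_cpg=params.n_cpg, seed=seed_anc)
        )
    tree = simulate_burst(SimConfig(params=params, target_n=target_n, seed=seed_tree))
    elements = evolve_sequences(tree, ancestor, params, seed=seed_seq)
    return tree, elements


def simulate_family(
    params: ModelParams, target_n: int, seed: int, ancestor: str | None = None
) -> ElementSet:
    """Present-day element set of one simulated burst (tree discarded)."""
    return simulate_tree_and_family(params, target_n, seed, ancestor)[1]


class RepeatFamilyModel:
    """Expansion-model inference for a family of repeat-element sequences.

    Parameters
    ----------
    sequences : ElementSet, (n, L) uint8 matrix, or iterable of strings
        Present-day element sequences.
    L : int
        Nominal element length used by the family-size estimator and the
        effective mutation rate (default 300).
    n_cpg : int
        CpG dinucleotide count of the ancestral element (default 24).
    cpg_factor : float
        CpG mutation-rate multiplier (default 6).
    delta : float
        Assumed fraction of active copies, used only to convert the fitted
        effective duplication rate delta*gamma into gamma (default 1).
    k_grid : iterable of int
        k values at which Hill exponents are estimated (default 5..90
        step 5).
    fit_window : (int, int)
        k range of the exponent-curve fit (default (35, 75)).
    s_min : int
        Tail cutoff of the Hill estimator (default 3).
    """

    def __init__(
        self,
        sequences,
        L: int = 300,
        n_cpg: int = 24,
        cpg_factor: float = 6.0,
        delta: float = 1.0,
        k_grid=None,
        fit_window: tuple[int, int] = (35, 75),
        s_min: int = 3,
        n_k_grid=None,
    ):
        if isinstance(sequences, ElementSet) or (
            isinstance(sequences, np.ndarray) and sequences.ndim == 2
        ):
            self.data = sequences
        else:
            seqs = [str(s).upper() for s in sequences]
            if not seqs:
                raise InputError("empty sequence collection")
            lengths = {len(s) for s in seqs}
            if len(lengths) == 1 and all(
                set(s) <= set("ACGT") for s in seqs
            ):
                self.data = np.vstack([encode(s) for s in seqs])
            else:
                self.data = seqs
        self.L = L
        self.n_cpg = n_cpg
        self.cpg_factor = cpg_factor
        self.delta = delta
        self.k_grid = list(k_grid) if k_grid is not None else list(range(5, 91, 5))
        self.n_k_grid = (
            list(n_k_grid) if n_k_grid is not None else list(range(5, 91))
        )
        self.fit_window = fit_window
        self.s_min = s_min

    @classmethod
    def from_fasta(cls, path, **kwargs) -> "RepeatFamilyModel":
        records = fileio.read_fasta(path)
        return cls([seq for _, seq in records], **kwargs)

    @property
    def n_sequences(self) -> int:
        if isinstance(self.data, ElementSet):
            return len(self.data)
        if isinstance(self.data, np.ndarray):
            return len(self.data)
        return len(self.data)

    def fit(self) -> "RepeatFamilyResults":
        """Run the inference chain and return a results object."""
        mu = effective_mu(self.L, self.n_cpg, self.cpg_factor)
        N_hat = estimate_N(self.data, k_values=self.n_k_grid, L=self.L)
        curve = exponent_curve(self.data, self.k_grid, s_min=self.s_min)
        fit = fit_ratio(curve, *self.fit_window)
        delta_gamma_hat = mu / fit.ratio_hat
        gamma_hat = delta_gamma_hat / self.delta
        params_hat = ModelParams(
            gamma=gamma_hat,
            delta=self.delta,
            cpg_factor=self.cpg_factor,
            L=self.L,
            n_cpg=self.n_cpg,
        )
        T1_hat = estimate_T1(N_hat, params_hat)
        return RepeatFamilyResults(
            model=self,
            mu=mu,
            N_hat=N_hat,
            curve=curve,
            fit_result=fit,
            delta_gamma_hat=delta_gamma_hat,
            gamma_hat=gamma_hat,
            T1_hat=T1_hat,
        )


@dataclass
class RepeatFamilyResults:
    """Estimates from one :meth:`RepeatFamilyModel.fit` call.

    All rates are in units of mu0, times in units of 1/mu0.
    """

    model: RepeatFamilyModel
    mu: float
    N_hat: float
    curve: ExponentCurve
    fit_result: FitResult
    delta_gamma_hat: float
    gamma_hat: float
    T1_hat: float
    t2_profile: T2Profile | None = None

    @property
    def ratio_hat(self) -> float:
        return self.fit_result.ratio_hat

    @property
    def ratio_stderr(self) -> float:
        """Seed-free dispersion proxy: residual RMS propagated through the
        local slope of alpha(k; r) at the window midpoint."""
        fit = self.fit_result
        k_mid = 0.5 * (fit.k_range[0] + fit.k_range[1])
        r = fit.ratio_hat
        dalpha_dr = k_mid / (1.0 - r * k_mid) ** 2
        rms = math.sqrt(fit.residual_norm / max(fit.n_points, 1))
        return rms / (dalpha_dr * math.sqrt(max(fit.n_points, 1)))

    def estimate_T2(
        self, T2_grid, seed: int, target_n: int | None = None, k_values=None, **kw
    ) -> T2Profile:
        """Grid-search T2 by re-simulating the fitted model (delta = 1) and
        matching log-binned spectra of the data; stores and returns the
        distance profile."""
        if target_n is None:
            target_n = int(round(self.N_hat))
        if k_values is None:
            k_values = [k for k in (40, 60) if k in self.model.k_grid]
            k_values = k_values or self.model.k_grid[:2]
        data = self.model.data
        matrix = data.matrix if isinstance(data, ElementSet) else data
        ref = {
            int(k): spectrum_from_counts(kmer_abundances(matrix, int(k)), int(k))
            for k in k_values
        }
        params = ModelParams(
            gamma=self.delta_gamma_hat,
            delta=1.0,
            cpg_factor=self.model.cpg_factor,
            T1=self.T1_hat,
            L=self.model.L,
            n_cpg=self.model.n_cpg,
        )
        self.t2_profile = fit_T2(
            ref, params, T2_grid, seed=seed, target_n=target_n, **kw
        )
        return self.t2_profile

    def summary(self) -> str:
        """Human-readable estimation report."""
        fit = self.fit_result
        lines = [
            "Repeat-family expansion model fit",
            "=" * 58,
            f"{'No. sequences':<34}{self.model.n_sequences:>24}",
            f"{'Effective mutation rate mu [mu0]':<34}{self.mu:>24.4f}",
            f"{'Family size N_hat':<34}{self.N_hat:>24.1f}",
            f"{'Tail cutoff s_min':<34}{self.curve.s_min:>24}",
            f"{'Fit window k':<34}{str(fit.k_range):>24}",
            f"{'Curve points fitted':<34}{fit.n_points:>24}",
            "-" * 58,
            f"{'mu/(delta*gamma) ratio_hat':<34}{self.ratio_hat:>24.6f}",
            f"{'  approx. std err':<34}{self.ratio_stderr:>24.6f}",
            f"{'delta*gamma_hat [mu0]':<34}{self.delta_gamma_hat:>24.2f}",
            f"{'gamma_hat [mu0] (delta={:.2f})'.format(self.model.delta):<34}"
            f"{self.gamma_hat:>24.2f}",
            f"{'T1_hat [1/mu0]':<34}{self.T1_hat:>24.6f}",
            f"{'Fit residual SSq':<34}{fit.residual_norm:>24.6f}",
        ]
        if self.t2_profile is not None:
            lines.append(
                f"{'T2_hat [1/mu0] (grid search)':<34}{self.t2_profile.best_t2:>24.6f}"
            )
        lines.append("=" * 58)
        lines.append("alpha_hat(k):")
        lines.append("    k   alpha_hat    n_tail   stderr")
        for k, a, n, se in zip(
            self.curve.k, self.curve.alpha, self.curve.n_tail, self.curve.stderr
        ):
            lines.append(f"  {k:>3}   {a:>9.4f}  {n:>8}   {se:.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "mu": self.mu,
            "N_hat": self.N_hat,
            "ratio_hat": self.ratio_hat,
            "ratio_stderr": self.ratio_stderr,
            "delta_gamma_hat": self.delta_gamma_hat,
            "gamma_hat": self.gamma_hat,
            "T1_hat": self.T1_hat,
            "fit_k_range": list(self.fit_result.k_range),
            "fit_residual_norm": self.fit_result.residual_norm,
            "fit_n_points": self.fit_result.n_points,
            "curve": {
                "k": self.curve.k.tolist(),
                "alpha_hat": self.curve.alpha.tolist(),
                "n_tail": self.curve.n_tail.tolist(),
            },
        }
        if self.t2_profile is not None:
            d["T2_hat"] = self.t2_profile.best_t2
            d["T2_grid"] = self.t2_profile.t2_grid.tolist()
            d["T2_distances"] = self.t2_profile.distances.tolist()
        return d


# ---------------------------------------------------------------------------
# one-command pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Configuration of the simulate -> count -> fit pipeline.

    Defaults are the model's standard study conditions: gamma = 200 (so
    delta*gamma = 200 mu0 at delta = 1), an Alu-like element (L = 300,
    24 CpGs, CpG factor 6), T2 = 0.024/mu0, k grid 5..90 step 5, Hill
    cutoff s_min = 3, fit window 35..75 and log binning above s = 7 with
    edge ratio 1.1885.  T1 < 0 means "derive from target_n by inverting
    the growth law".
    """

    gamma: float = 200.0
    delta: float = 1.0
    cpg_factor: float = 6.0
    T1: float = -1.0
    T2: float = 0.024
    L: int = 300
    n_cpg: int = 24
    target_n: int = 10_000
    k_grid: str = "5:90:5"
    s_min: int = 3
    fit_k_lo: int = 35
    fit_k_hi: int = 75
    bin_threshold: int = 7
    bin_ratio: float = 1.1885
    seed: int = 0
    outdir: str = "repeatburst_out"
    ancestor_fasta: str | None = None

    def k_values(self) -> list[int]:
        lo, hi, step = (int(x) for x in self.k_grid.split(":"))
        return list(range(lo, hi + 1, step))

    def params(self) -> ModelParams:
        T1 = self.T1
        if T1 < 0:
            probe = ModelParams(
                gamma=self.gamma, delta=self.delta, cpg_factor=self.cpg_factor,
                L=self.L, n_cpg=self.n_cpg,
            )
            T1 = estimate_T1(self.target_n, probe)
        return ModelParams(
            gamma=self.gamma,
            delta=self.delta,
            cpg_factor=self.cpg_factor,
            T1=T1,
            T2=self.T2,
            L=self.L,
            n_cpg=self.n_cpg,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls(**json.loads(text))


def run_pipeline(config: PipelineConfig) -> dict:
    """simulate_burst -> evolve_sequences -> spectra -> Hill -> ratio fit.

    Writes ancestor FASTA, Newick tree, element FASTA, per-k spectrum TSVs,
    the exponent-curve TSV, a JSON fit report and a stage log into
    ``config.outdir``; returns the report dict.  Fully deterministic per
    seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = fileio.config_hash(asdict(config))
    params = config.params()
    rates = params.rates()
    if all(rates.mu * k >= rates.delta_gamma for k in config.k_values()):
        from .errors import NoPowerLawTailError

        raise NoPowerLawTailError(
            f"no requested k has a power-law tail: mu={rates.mu:g}, "
            f"delta*gamma={rates.delta_gamma:g}, k_grid={config.k_grid}"
        )
    meta = {"produced_by": "repeatburst pipeline", "config": chash, "seed": config.seed}
    log_lines = [f"config_hash={chash}", f"seed={config.seed}", f"params={params.to_dict()}"]
    t0 = _time.perf_counter()

    def log_stage(name: str) -> None:
        log_lines.append(f"{name}: t={_time.perf_counter() - t0:.2f}s")

    if config.ancestor_fasta:
        ancestor = fileio.read_fasta(config.ancestor_fasta)[0][1]
        if len(ancestor) != config.L:
            raise InputError(
                f"ancestor length {len(ancestor)} != configured L={config.L}"
            )
    else:
        seed_anc = _spawn_seeds(config.seed, 4)[3]
        ancestor = make_ancestral(
            AncestorSpec(L=config.L, n_cpg=config.n_cpg, seed=seed_anc)
        )
    fileio.write_fasta([("ancestor", ancestor)], outdir / "ancestor.fasta", meta)
    log_stage("ancestor")

    tree, elements = simulate_tree_and_family(
        params, config.target_n, config.seed, ancestor=ancestor
    )
    fileio.write_newick(tree, outdir / "tree.nwk", meta)
    fileio.write_fasta(
        zip(elements.leaf_ids, elements.sequences), outdir / "elements.fasta", meta
    )
    log_stage("simulate")

    for k in config.k_values():
        sp = spectrum_from_counts(kmer_abundances(elements.matrix, k), k)
        fileio.write_spectrum_tsv(sp, outdir / f"spectrum_k{k}.tsv", meta)
        binned = log_bin(sp, threshold=config.bin_threshold, ratio=config.bin_ratio)
        fileio.write_spectrum_tsv(binned, outdir / f"spectrum_k{k}_binned.tsv", meta)
    log_stage("spectra")

    model = RepeatFamilyModel(
        elements,
        L=config.L,
        n_cpg=config.n_cpg,
        cpg_factor=config.cpg_factor,
        delta=config.delta,
        k_grid=config.k_values(),
        fit_window=(config.fit_k_lo, config.fit_k_hi),
        s_min=config.s_min,
    )
    results = model.fit()
    fileio.write_curve_tsv(results.curve, outdir / "exponent_curve.tsv", meta)
    log_stage("fit")

    report = {
        "config_hash": chash,
        "seed": config.seed,
        "true_params": params.to_dict(),
        "true_ratio": params.rates().ratio,
        "estimates": results.to_dict(),
        "summary": results.summary(),
    }
    (outdir / "fit_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (outdir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return report
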