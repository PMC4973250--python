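"""Sequence evolution: site-level Markov law, CpG hypermutability, bookkeeping."""

import math

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import chisquare

from repeatburst import (
    InputError,
    ModelParams,
    SimConfig,
    evolve_sequences,
    make_ancestral,
    pairwise_divergence,
    simulate_burst,
)
from repeatburst.seqevo import _evolve_edge, encode, decode
from repeatburst.synthetic import AncestorSpec


def _single_edge_tree(t: float, params: ModelParams):
    """A one-leaf 'tree': the founder evolving alone for a time t."""
    p = ModelParams(
        gamma=params.gamma, delta=params.delta, mu0=params.mu0,
        cpg_factor=params.cpg_factor, T1=0.0, T2=t, L=params.L, n_cpg=params.n_cpg,
    )
    return simulate_burst(SimConfig(params=p, target_n=1, seed=0))


def test_no_mutation_preserves_everything(small_tree):
    params = ModelParams(gamma=10.0, delta=0.5, mu0=1.0, T1=0.5, T2=0.2)
    anc = make_ancestral(AncestorSpec(L=120, n_cpg=10, seed=4))
    # mu0 = 0 is outside ModelParams' domain, so freeze mutation by
    # evolving for zero time instead: T1 = T2 = 0 single-leaf tree
    tree = _single_edge_tree(0.0, params)
    out = evolve_sequences(tree, anc, seed=1)
    assert out.sequences == [anc]


def test_length_and_alphabet_conserved(small_tree):
    anc = make_ancestral(AncestorSpec(L=150, n_cpg=12, seed=2))
    out = evolve_sequences(small_tree, anc, seed=5)
    assert out.matrix.shape == (50, 150)
    assert set(np.unique(out.matrix)) <= {0, 1, 2, 3}


def test_rejects_non_acgt_ancestor(small_tree):
    with pytest.raises(InputError):
        evolve_sequences(small_tree, "ACGTNNNACGT", seed=0)


def test_encode_decode_roundtrip():
    s = "ACGTACGTTTGC"
    assert decode(encode(s)) == s


class TestPairwiseDivergence:
    def test_identical(self):
        assert pairwise_divergence("ACGT", "ACGT") == 0.0

    def test_one_of_four(self):
        assert pairwise_divergence("ACGT", "ACGA") == 0.25

    def test_length_mismatch(self):
        with pytest.raises(InputError):
            pairwise_divergence("ACG", "ACGT")


def test_single_site_markov_law_matches_matrix_exponential():
    """Without CpG coupling the per-site process is the 4-state chain with
    uniform rate mu0/3 to each alternative; identity probability follows
    the matrix exponential 1/4 + 3/4 exp(-4/3 mu0 t)."""
    t = 0.05
    params = ModelParams(gamma=1.0, delta=1.0, cpg_factor=1.0, L=300, n_cpg=0)
    Q = np.full((4, 4), 1.0 / 3.0)
    np.fill_diagonal(Q, -1.0)
    p_same = expm(Q * t)[0, 0]

    anc = make_ancestral(AncestorSpec(L=2000, n_cpg=0, seed=9))
    tree = _single_edge_tree(t, params)
    n_sites = 0
    n_same = 0
    rng = np.random.default_rng(77)
    for rep in range(60):
        out = evolve_sequences(tree, anc, params=params, rng=rng)
        n_sites += 2000
        n_same += int((out.matrix[0] == encode(anc)).sum())
    frac = n_same / n_sites
    se = math.sqrt(p_same * (1 - p_same) / n_sites)
    assert abs(frac - p_same) < 3 * se


def test_pair_divergence_matches_two_branch_closed_form():
    """Two leaves separated by total path 2t: P(differ) from the two-step
    matrix exponential of the uniform chain."""
    t = 0.04
    params = ModelParams(gamma=50.0, delta=1.0, cpg_factor=1.0, L=1500, n_cpg=0)
    Q = np.full((4, 4), 1.0 / 3.0)
    np.fill_diagonal(Q, -1.0)
    p_same = expm(Q * 2 * t)[0, 0]

    anc = make_ancestral(AncestorSpec(L=1500, n_cpg=0, seed=10))
    p = ModelParams(gamma=50.0, delta=1.0, cpg_factor=1.0, T1=0.0, T2=t, L=1500, n_cpg=0)
    divs = []
    n_sites = 0
    for seed in range(40):
        tree = simulate_burst(SimConfig(params=p, target_n=2, seed=seed))
        out = evolve_sequences(tree, anc, params=p, seed=1000 + seed)
        divs.append(pairwise_divergence(out.matrix[0], out.matrix[1]))
        n_sites += 1500
    mean_div = float(np.mean(divs))
    se = math.sqrt(p_same * (1 - p_same) / n_sites)
    assert abs(mean_div - (1 - p_same)) < 3 * se


def test_cpg_letters_carry_sixfold_total_rate():
    """On an all-CG sequence the deamination channel must fire 5x as often
    as the background channel (total rate 6 mu0 per CpG letter)."""
    params = ModelParams(gamma=1.0, delta=1.0, cpg_factor=6.0, L=300, n_cpg=75)
    seq0 = encode("CG" * 150)
    rng = np.random.default_rng(5)
    counter = [0, 0]
    for _ in range(15_000):
        _evolve_edge(seq0.copy(), 1e-4, params, rng, counter)
    bg, deam = counter
    # expected bg : deam = 300 : 1500 (every site gains 5 mu0 extra)
    ratio = deam / bg
    se = 5.0 * math.sqrt(1.0 / bg + 1.0 / deam)
    assert abs(ratio - 5.0) < 3 * se


def test_realized_rate_matches_effective_mu_on_alu_like_ancestor():
    """Total event rate per site per unit time on a fresh L=300, 24-CpG
    ancestor is the CpG-weighted average 1.8 mu0."""
    params = ModelParams(gamma=1.0, delta=1.0, cpg_factor=6.0, L=300, n_cpg=24)
    anc = encode(make_ancestral(AncestorSpec(L=300, n_cpg=24, seed=21)))
    t = 1e-3  # short edges: context decay is negligible
    reps = 12_000
    rng = np.random.default_rng(6)
    counter = [0, 0]
    for _ in range(reps):
        _evolve_edge(anc.copy(), t, params, rng, counter)
    events = counter[0] + counter[1]
    expected = 1.8 * 300 * t * reps
    se = math.sqrt(expected)  # Poisson
    assert abs(events - expected) < 3 * se


def test_uniform_limit_has_unbiased_substitution_targets():
    """With cpg_factor = 1 the process is the uniform 3-alternative model:
    no deamination events, and C mutates to A/G/T uniformly."""
    params = ModelParams(gamma=1.0, delta=1.0, cpg_factor=1.0, L=1000, n_cpg=0)
    seq0 = np.full(1000, 1, dtype=np.uint8)  # all C
    rng = np.random.default_rng(8)
    counter = [0, 0]
    targets = {0: 0, 2: 0, 3: 0}
    for _ in range(120):
        seq = seq0.copy()
        _evolve_edge(seq, 0.05, params, rng, counter)
        for b in (0, 2, 3):
            targets[b] += int((seq == b).sum())
    assert counter[1] == 0  # no deamination channel
    counts = [targets[0], targets[2], targets[3]]
    assert chisquare(counts).pvalue > 1e-3


def test_dynamic_cpg_context_gains_and_loses_hypermutability():
    """A 'C' placed in front of a 'G' by mutation becomes deaminating:
    evolve 'CA' -> occasionally 'CG'; deamination events can then occur,
    which is only possible if context is re-evaluated on the fly."""
    params = ModelParams(gamma=1.0, delta=1.0, cpg_factor=6.0, L=2, n_cpg=0)
    rng = np.random.default_rng(42)
    counter = [0, 0]
    for _ in range(6000):
        _evolve_edge(encode("CA"), 0.5, params, rng, counter)
    assert counter[1] > 0
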