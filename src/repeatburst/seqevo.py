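"""Sequence evolution along the burst genealogy with hypermutable CpGs.

Sites follow a continuous-time Markov process: every nucleotide changes to
one of the other three with total background rate mu0 (uniform over
targets).  In addition a C that is immediately followed by G, and a G that
is immediately preceded by C, carry an extra deamination channel (C->T,
G->A) with rate (cpg_factor - 1) * mu0, so the *total* rate at a CpG
position is cpg_factor * mu0 (default 6 mu0).  CpG context is dynamic: a CG
created by mutation becomes hypermutable, a destroyed one reverts to
background.  Only the literal "CG" on the stored strand counts.

The per-edge simulation is an exact Gillespie scheme over the whole
sequence: waiting times are exponential with the current total rate
mu0 * (L + 2 * (cpg_factor - 1) * #CG), and each event is either a
background substitution at a uniform position or a deamination at a uniform
CpG letter.  A swap-pop index over CpG start positions keeps every event
O(1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .theory import ModelParams
from .treesim import NO_PARENT, BranchingTree

__all__ = [
    "ElementSet",
    "evolve_sequences",
    "pairwise_divergence",
    "encode",
    "decode",
]

ALPHABET = "ACGT"
A, C, G, T = 0, 1, 2, 3
_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Map an A/C/G/T string to a uint8 array (0..3). Case-insensitive."""
    arr = _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted({ch for ch in seq.upper() if ch not in ALPHABET})
        raise InputError(f"sequence contains non-ACGT characters: {bad}")
    return arr


def decode(arr: np.ndarray) -> str:
    return "".join(ALPHABET[b] for b in arr)


@dataclass
class ElementSet:
    """Present-day repeat sequences, all descended from one ancestor.

    ``matrix`` holds the leaf sequences as an (n, L) uint8 array in leaf
    order; ``sequences`` decodes them on demand.  No indels exist in the
    model, so every row has the ancestor's length.
    """

    matrix: np.ndarray
    ancestor: str
    params: ModelParams
    leaf_ids: list[str] | None = None
    # realized Gillespie event tallies over the whole tree
    # [background substitutions, CpG deaminations]; None if not tracked
    mutation_events: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.ancestor):
            raise InputError("sequence matrix shape does not match ancestor length")
        if self.leaf_ids is None:
            self.leaf_ids = [f"elem_{i}" for i in range(len(self.matrix))]

    def __len__(self) -> int:
        return len(self.matrix)

    @property
    def sequences(self) -> list[str]:
        return [decode(row) for row in self.matrix]


def _cpg_index(seq: np.ndarray) -> tuple[list[int], dict[int, int]]:
    """Positions i with seq[i:i+2] == CG, as swap-pop list + position->slot map."""
    starts = np.flatnonzero((seq[:-1] == C) & (seq[1:] == G))
    lst = [int(i) for i in starts]
    return lst, {p: j for j, p in enumerate(lst)}


def _evolve_edge(
    seq: np.ndarray,
    duration: float,
    params: ModelParams,
    rng: np.random.Generator,
    counter: list[int] | None = None,
) -> None:
    """Mutate ``seq`` in place for a time ``duration`` (exact Gillespie).

    ``counter``, when given, receives [n_background, n_deamination] event
    tallies (used by rate-validation tests).
    """
    if duration <= 0.0 or params.mu0 == 0.0:
        return
    L = len(seq)
    extra = params.cpg_factor - 1.0  # deamination rate per CpG letter, units mu0
    cpg, slot = _cpg_index(seq)

    def drop(p: int) -> None:
        j = slot.pop(p, None)
        if j is None:
            return
        last = cpg.pop()
        if j < len(cpg):
            cpg[j] = last
            slot[last] = j

    def add(p: int) -> None:
        if p not in slot:
            slot[p] = len(cpg)
            cpg.append(p)

    def refresh(p: int) -> None:
        """Re-evaluate CpG status of the dinucleotide starting at position p."""
        if p < 0 or p + 1 >= L:
            return
        if seq[p] == C and seq[p + 1] == G:
            add(p)
        else:
            drop(p)

    t = 0.0
    while True:
        n_cpg_letters = 2 * len(cpg)
        total_rate = params.mu0 * (L + extra * n_cpg_letters)
        t += rng.exponential(1.0 / total_rate)
        if t > duration:
            return
        if rng.random() * (L + extra * n_cpg_letters) < L:
            # background substitution: uniform position, uniform other base
            pos = int(rng.integers(L))
            seq[pos] = (seq[pos] + 1 + rng.integers(3)) % 4
            if counter is not None:
                counter[0] += 1
        else:
            # deamination at a uniform CpG letter: C->T or G->A
            start = cpg[int(rng.integers(len(cpg)))]
            if rng.random() < 0.5:
                pos = start
                seq[pos] = T
            else:
                pos = start + 1
                seq[pos] = A
            if counter is not None:
                counter[1] += 1
        # a change at pos can create/destroy the CG pairs (pos-1,pos), (pos,pos+1)
        refresh(pos - 1)
        refresh(pos)


def evolve_sequences(
    tree: BranchingTree,
    ancestor: str,
    params: ModelParams | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ElementSet:
    """Evolve the ancestor along every edge of a finalized tree.

    Returns one present-day sequence per leaf, in leaf-index order.  The
    traversal is an explicit preorder stack carrying one sequence copy per
    path, so memory stays O(depth * L).
    """
    if params is None:
        params = tree.params
    if not ancestor:
        raise InputError("ancestor sequence is empty")
    root_seq = encode(ancestor)
    if rng is None:
        rng = np.random.default_rng(seed)

    n = tree.n_nodes
    lengths = tree.edge_lengths()
    counter = [0, 0]
    leaf_rows: dict[int, np.ndarray] = {}
    stack: list[tuple[int, np.ndarray]] = [(0, root_seq.copy())]
    while stack:
        node, seq = stack.pop()
        _evolve_edge(seq, float(lengths[node]), params, rng, counter)
        c0, c1 = tree.children[node]
        if c0 == NO_PARENT:
            leaf_rows[node] = seq
        else:
            stack.append((int(c0), seq))
            stack.append((int(c1), seq.copy()))

    leaves = tree.leaf_indices
    matrix = np.vstack([leaf_rows[int(i)] for i in leaves])
    ids = [f"elem_{int(i)}" for i in leaves]
    return ElementSet(
        matrix=matrix,
        ancestor=ancestor,
        params=params,
        leaf_ids=ids,
        mutation_events=(counter[0], counter[1]),
    )


def pairwise_divergence(a: str | np.ndarray, b: str | np.ndarray) -> float:
    """Hamming distance divided by length, in [0, 1]."""
    av = encode(a) if isinstance(a, str) else a
    bv = encode(b) if isinstance(b, str) else b
    if len(av) != len(bv):
        raise InputError(f"length mismatch: {len(av)} vs {len(bv)}")
    if len(av) == 0:
        raise InputError("empty sequences")
    return float(np.count_nonzero(av != bv)) / len(av)
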