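"""Kinetic Monte Carlo simulation of the duplication burst.

The burst is a continuous-time branching process: every *active* element
duplicates at rate gamma, so the aggregate event rate is gamma * (number of
active elements).  Waiting times are exponential with that rate; at each
event a uniformly random active element duplicates.  The duplication is
stored as a binary node: one child continues the parent element (keeping its
active flag), the other is the new copy, active with probability delta.

The simulation stops at the first event that brings the total element count
to ``target_n`` (exact hit, for reproducibility).  All edge lengths are then
rescaled by a common factor so the root-to-last-event height equals T1, and
every terminal edge is extended by T2, so all leaves sit at depth T1 + T2.

Trees are stored in flat numpy arrays (parent pointers + node times), which
keeps a 10^5-leaf burst cheap to build and traverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, SimulationError
from .theory import ModelParams

__all__ = [
    "SimConfig",
    "BranchingTree",
    "simulate_burst",
    "counts_at_time",
    "subtree_sizes",
    "sample_burst_size",
]

NO_PARENT = -1


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one burst simulation: parameters, stop size, seed."""

    params: ModelParams
    target_n: int
    seed: int

    def __post_init__(self) -> None:
        if self.target_n < 1:
            raise DomainError(f"target_n must be >= 1, got {self.target_n}")


class BranchingTree:
    """Timed duplication genealogy of one burst.

    Nodes are indexed 0..2M where M is the number of duplication events:
    node 0 is the root (start of the founder lineage at time 0 -- its edge is
    the founder's pre-first-duplication lifetime), internal nodes are
    duplication events, leaves are present-day elements.  Arrays:

    parent : int array, parent node index (NO_PARENT for the root).
    time : float array, absolute time of the node (duplication time for
        internal nodes, T1 + T2 for leaves after finalization).
    active : bool array, whether the *edge above* the node belongs to an
        active element (the root edge is always active).
    children : (n_nodes, 2) int array; row [c_cont, c_new] for internal
        nodes, [-1, -1] for leaves.  c_cont continues the parent element's
        identity, c_new is the fresh copy.
    """

    def __init__(
        self,
        parent: np.ndarray,
        time: np.ndarray,
        active: np.ndarray,
        children: np.ndarray,
        params: ModelParams,
        raw_stop_time: float = float("nan"),
    ):
        self.parent = parent
        self.time = time
        self.active = active
        self.children = children
        self.params = params
        # KMC time of the event that reached target_n, before rescaling
        self.raw_stop_time = raw_stop_time

    # -- basic structure -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def is_leaf(self) -> np.ndarray:
        return self.children[:, 0] == NO_PARENT

    @property
    def n_leaves(self) -> int:
        return int(self.is_leaf.sum())

    @property
    def leaf_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_leaf)

    @property
    def internal_indices(self) -> np.ndarray:
        """Duplication events (excludes the root stem node)."""
        return np.flatnonzero(~self.is_leaf)

    @property
    def height(self) -> float:
        return self.params.T1 + self.params.T2

    def edge_length(self, node: int) -> float:
        p = self.parent[node]
        return float(self.time[node]) if p == NO_PARENT else float(
            self.time[node] - self.time[p]
        )

    def edge_lengths(self) -> np.ndarray:
        """Length of the edge above every node (root edge starts at time 0)."""
        parent_time = np.where(self.parent == NO_PARENT, 0.0, self.time[self.parent])
        return self.time - parent_time

    # -- exports ----------------------------------------------------------

    def to_newick(self, precision: int = 10) -> str:
        """Newick string with branch lengths and ``[&active=0/1]`` comments.

        Iterative post-order assembly (safe for caterpillar trees deeper
        than the recursion limit).
        """
        lengths = self.edge_lengths()
        out: dict[int, str] = {}
        # stack of (node, expanded?)
        stack: list[tuple[int, bool]] = [(0, False)]
        while stack:
            node, expanded = stack.pop()
            c0, c1 = self.children[node]
            if c0 == NO_PARENT:
                out[node] = (
                    f"n{node}[&active={int(self.active[node])}]"
                    f":{lengths[node]:.{precision}g}"
                )
            elif not expanded:
                stack.append((node, True))
                stack.append((int(c0), False))
                stack.append((int(c1), False))
            else:
                s0, s1 = out.pop(int(c0)), out.pop(int(c1))
                out[node] = (
                    f"({s0},{s1})[&active={int(self.active[node])}]"
                    f":{lengths[node]:.{precision}g}"
                )
        return out[0] + ";"


def simulate_burst(config: SimConfig) -> BranchingTree:
    """Run one KMC burst to exactly ``target_n`` elements and finalize.

    Returns a tree whose leaves are the ``target_n`` present-day elements,
    rescaled so that the last duplication event sits at T1 and every leaf at
    T1 + T2.  Raises :class:`SimulationError` if the target is unreachable
    within ``100 * target_n`` events (cannot happen for delta > 0 or a
    reachable founder-only cascade, but guards degenerate configs).
    """
    params = config.params
    target_n = config.target_n
    rng = np.random.default_rng(config.seed)

    n_events = target_n - 1
    n_nodes = 1 + 2 * n_events  # root + (each event adds: 1 node split into 2)
    parent = np.full(n_nodes, NO_PARENT, dtype=np.int64)
    time = np.zeros(n_nodes, dtype=np.float64)
    active = np.ones(n_nodes, dtype=bool)
    children = np.full((n_nodes, 2), NO_PARENT, dtype=np.int64)

    # Tips of the growing tree: node index of each living element's current
    # edge end.  Active tips are eligible for duplication.
    active_tips: list[int] = [0]
    t = 0.0
    next_node = 1
    events_done = 0
    max_events = 100 * target_n
    iterations = 0

    while events_done < n_events:
        iterations += 1
        if iterations > max_events or not active_tips:
            raise SimulationError(
                f"target_n={target_n} unreachable: {events_done + 1} elements "
                f"after {iterations - 1} events, {len(active_tips)} active"
            )
        a = len(active_tips)
        t += rng.exponential(1.0 / (params.gamma * a))
        i = rng.integers(a)
        node = active_tips[i]
        # duplication: `node` becomes an internal event node at time t
        time[node] = t
        c_cont, c_new = next_node, next_node + 1
        next_node += 2
        parent[c_cont] = node
        parent[c_new] = node
        children[node, 0] = c_cont
        children[node, 1] = c_new
        active[c_cont] = active[node]  # continuing lineage keeps its status
        active[c_new] = rng.random() < params.delta
        # replace the duplicating tip by its continuation; add the new copy
        active_tips[i] = c_cont
        if active[c_new]:
            active_tips.append(c_new)
        events_done += 1

    # finalize: rescale so the last event sits at T1, extend tips by T2
    leaf = children[:, 0] == NO_PARENT
    if events_done > 0:
        scale = params.T1 / t
        time[~leaf] *= scale
    time[leaf] = params.T1 + params.T2
    return BranchingTree(parent, time, active, children, params, raw_stop_time=t)


def counts_at_time(tree: BranchingTree, t: float) -> tuple[int, int]:
    """(total, active) element counts at absolute time t in [0, T1 + T2].

    total = 1 + number of duplication events at time <= t; active counts
    edges flagged active whose lifetime interval contains t.
    """
    if not 0.0 <= t <= tree.height + 1e-12:
        raise DomainError(f"t={t} outside [0, {tree.height}]")
    internal = tree.internal_indices
    total = 1 + int(np.count_nonzero(tree.time[internal] <= t))
    parent_time = np.where(tree.parent == NO_PARENT, 0.0, tree.time[tree.parent])
    crossing = (parent_time <= t) & (t < tree.time) | (
        tree.is_leaf & (t >= tree.time)  # leaf edges persist at the final instant
    )
    active_n = int(np.count_nonzero(crossing & tree.active))
    return total, active_n


def subtree_sizes(tree: BranchingTree) -> np.ndarray:
    """Present-day descendant count of the *new copy* of every duplication.

    One entry per internal (event) node: the number of leaves below the
    child that was created at that event.  In a delta = 1 burst the tail of
    this clone-size distribution decays with exponent 2, the mutation-free
    limit of the abundance-tail exponent.
    """
    n = tree.n_nodes
    sizes = np.zeros(n, dtype=np.int64)
    sizes[tree.is_leaf] = 1
    # nodes were allocated in birth order, so children have larger indices;
    # a reverse index sweep is a valid post-order accumulation
    for node in range(n - 1, 0, -1):
        sizes[tree.parent[node]] += sizes[node]
    return sizes[tree.children[tree.internal_indices, 1]]


def sample_burst_size(params: ModelParams, t: float, rng: np.random.Generator) -> int:
    """Total element count of one unscaled KMC burst run for a time t.

    Monte-Carlo counterpart of :func:`repeatburst.theory.expected_copies`;
    only counts are tracked, so large ensembles are cheap.
    """
    if t < 0:
        raise DomainError(f"t must be >= 0, got {t}")
    total = 1
    n_active = 1
    clock = 0.0
    while n_active > 0:
        clock += rng.exponential(1.0 / (params.gamma * n_active))
        if clock > t:
            break
        total += 1
        if rng.random() < params.delta:
            n_active += 1
    return total
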