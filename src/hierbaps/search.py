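"""Greedy stochastic search for the maximum-likelihood partition.

Three move families are cycled to convergence: single-sequence
reassignment, pairwise cluster merges, and relocation of complete-linkage
subgroups.  Acceptance is strictly greedy — a move is applied only when it
increases the log marginal likelihood by more than a small tolerance —
while stochasticity is confined to the visit order of sequences and to the
perturbed initial partitions of the restarts, so results are fully
reproducible from the seed.
"""

from __future__ import annotations

import numpy as np
from joblib import Parallel, delayed
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .alignment import MISSING, SnpMatrix
from .likelihood import (
    IMPROVEMENT_TOL,
    Partition,
    SearchState,
    apply_move,
    cluster_contributions,
    partition_log_ml,
)

#: Fraction of sequences randomly reassigned when perturbing a restart.
_PERTURB_FRACTION = 0.25


def snp_hamming_distances(snp: SnpMatrix) -> np.ndarray:
    """Pairwise SNP distances: mismatching loci among the jointly observed.

    Pairs with no jointly observed locus get the maximal distance M, so
    they are merged last by the agglomeration.
    """
    codes = snp.codes
    observed = codes != MISSING
    n, m = codes.shape
    dist = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        shared = observed[i][None, :] & observed
        mism = (codes[i][None, :] != codes) & shared
        d = mism.sum(axis=1).astype(np.float64)
        d[shared.sum(axis=1) == 0] = float(m)
        dist[i] = d
    np.fill_diagonal(dist, 0.0)
    return dist


def initialize_partition(snp: SnpMatrix, k_init: int) -> Partition:
    """Complete-linkage initial partition from pairwise SNP distances.

    The dendrogram is cut to ``min(k_init, number of distinct sequences)``
    clusters; identical sequences always co-cluster at distance zero and
    may leave fewer clusters than requested.
    """
    if k_init < 1:
        raise ValueError(f"k_init must be >= 1, got {k_init}")
    n = snp.n_sequences
    k_init = min(k_init, n)
    if k_init == 1:
        return Partition(labels=np.ones(n, dtype=np.int64), k_max=1)
    dist = snp_hamming_distances(snp)
    n_distinct = np.unique(snp.codes, axis=0).shape[0]
    k_eff = min(k_init, n_distinct)
    tree = linkage(squareform(dist, checks=False), method="complete")
    raw = fcluster(tree, t=k_eff, criterion="maxclust")
    return Partition(labels=Partition.compact(raw), k_max=k_init)


# ---------------------------------------------------------------------------
# Move family 1: single-sequence reassignment
# ---------------------------------------------------------------------------

def sweep_reassign_individuals(state: SearchState) -> SearchState:
    """Greedily move single sequences to their best cluster.

    Sequences are visited in an rng-shuffled order; each is moved to the
    destination (including a new singleton cluster while K < K_max) with
    the largest strictly positive log-ML gain, applied immediately.
    Passes repeat until one completes with no move.
    """
    n = state.snp.n_sequences
    while True:
        moved = False
        for s in state.rng.permutation(n):
            f = int(state.labels[s])
            d_rem = state.delta_remove(s)
            gains = state.delta_add(s)
            gains[f - 1] = -np.inf
            best_to = int(np.argmin(-gains)) + 1  # lowest index on ties
            best = d_rem + gains[best_to - 1]
            if state.k < state.k_max and state.cluster_sizes[f - 1] > 1:
                new_gain = d_rem + state.delta_add_new(s)
                if new_gain > best + IMPROVEMENT_TOL:
                    best, best_to = new_gain, state.k + 1
            if best > IMPROVEMENT_TOL:
                apply_move(state, int(s), best_to)
                moved = True
        if not moved:
            return state


# ---------------------------------------------------------------------------
# Move family 2: pairwise cluster merges
# ---------------------------------------------------------------------------

def sweep_merge_clusters(state: SearchState) -> SearchState:
    """Greedily apply the best strictly-improving pairwise cluster merge."""
    while state.k >= 2:
        k = state.k
        pairs = [(i, j) for i in range(k - 1) for j in range(i + 1, k)]
        merged = np.stack([state.counts[i] + state.counts[j] for i, j in pairs])
        contribs = cluster_contributions(merged, state.alpha)
        deltas = np.array(
            [
                contribs[p] - state.cluster_log_ml[i] - state.cluster_log_ml[j]
                for p, (i, j) in enumerate(pairs)
            ]
        )
        best = int(np.argmax(deltas))
        if deltas[best] <= IMPROVEMENT_TOL:
            return state
        i, j = pairs[best]
        _merge_clusters(state, i, j, contribs[best])
    return state


def _merge_clusters(state: SearchState, i: int, j: int, new_contrib: float) -> None:
    state.counts[i] += state.counts[j]
    state.cluster_sizes[i] += state.cluster_sizes[j]
    state.cluster_log_ml[i] = new_contrib
    state.counts = np.delete(state.counts, j, axis=0)
    state.cluster_sizes = np.delete(state.cluster_sizes, j)
    state.cluster_log_ml = np.delete(state.cluster_log_ml, j)
    state.labels[state.labels == j + 1] = i + 1
    state.labels[state.labels > j + 1] -= 1
    state.log_ml = float(state.cluster_log_ml.sum())
    state.history.append(state.log_ml)


# ---------------------------------------------------------------------------
# Move family 3: relocation of complete-linkage subgroups
# ---------------------------------------------------------------------------

def _linkage_subgroups(members: np.ndarray, dist: np.ndarray) -> list[np.ndarray]:
    """Member subsets at every node of the complete-linkage subtree
    (leaves and internal nodes; the root is excluded)."""
    m = members.size
    sub = dist[np.ix_(members, members)]
    tree = linkage(squareform(sub, checks=False), method="complete")
    clades: list[list[int]] = [[i] for i in range(m)]
    for a, b, _, _ in tree:
        clades.append(clades[int(a)] + clades[int(b)])
    return [members[np.sort(c)] for c in clades[:-1]]


def _group_counts(state: SearchState, group: np.ndarray) -> np.ndarray:
    counts = np.zeros(state.counts.shape[1:], dtype=np.int64)
    codes = state.snp.codes[group]
    rows, cols = np.nonzero(codes != MISSING)
    np.add.at(counts, (cols, codes[rows, cols]), 1)
    return counts


def sweep_split_relocate(state: SearchState, dist: np.ndarray | None = None) -> SearchState:
    """Relocate complete-linkage subgroups of large clusters.

    For every cluster of size >= 4, candidate subgroups are read off the
    nodes of the cluster's own complete-linkage subtree; each is scored
    against every other cluster and (while K < K_max) against a new
    cluster.  The single best strictly-improving relocation is applied and
    the scan repeats until none remains.  This is the move that lets the
    search undo a bad agglomerative start by splitting a mixed cluster.
    """
    if dist is None:
        dist = snp_hamming_distances(state.snp)
    while True:
        best_delta = IMPROVEMENT_TOL
        best_plan = None
        for c in range(state.k):
            if state.cluster_sizes[c] < 4:
                continue
            members = np.flatnonzero(state.labels == c + 1)
            for group in _linkage_subgroups(members, dist):
                if group.size == members.size:
                    continue
                g_counts = _group_counts(state, group)
                src_after = cluster_contributions(
                    (state.counts[c] - g_counts)[None], state.alpha
                )[0]
                d_src = src_after - state.cluster_log_ml[c]
                dest_blocks = state.counts + g_counts[None]
                dest_contribs = cluster_contributions(dest_blocks, state.alpha)
                d_dest = dest_contribs - state.cluster_log_ml
                d_dest[c] = -np.inf
                deltas = d_src + d_dest
                t = int(np.argmax(deltas))
                if deltas[t] > best_delta:
                    best_delta = float(deltas[t])
                    best_plan = (c, group, t, g_counts)
                if state.k < state.k_max:
                    new_delta = d_src + cluster_contributions(
                        g_counts[None], state.alpha
                    )[0]
                    if new_delta > best_delta:
                        best_delta = float(new_delta)
                        best_plan = (c, group, state.k, g_counts)
        if best_plan is None:
            return state
        _relocate_group(state, *best_plan)


def _relocate_group(
    state: SearchState, src: int, group: np.ndarray, dest: int, g_counts: np.ndarray
) -> None:
    if dest == state.k:  # open a new cluster
        state.counts = np.concatenate(
            [state.counts, np.zeros((1,) + state.counts.shape[1:], dtype=np.int64)]
        )
        state.cluster_sizes = np.append(state.cluster_sizes, 0)
        state.cluster_log_ml = np.append(state.cluster_log_ml, 0.0)
    state.counts[src] -= g_counts
    state.counts[dest] += g_counts
    state.cluster_sizes[src] -= group.size
    state.cluster_sizes[dest] += group.size
    state.labels[group] = dest + 1
    pair = cluster_contributions(state.counts[[src, dest]], state.alpha)
    state.cluster_log_ml[src] = pair[0]
    state.cluster_log_ml[dest] = pair[1]
    state.log_ml = float(state.cluster_log_ml.sum())
    state.history.append(state.log_ml)


# ---------------------------------------------------------------------------
# Full search
# ---------------------------------------------------------------------------

def _single_search(snp: SnpMatrix, k_max: int, seed: int, restart: int) -> tuple[np.ndarray, float]:
    rng = np.random.default_rng(seed + restart)
    init = initialize_partition(snp, k_max)
    labels = init.labels
    if restart > 0:
        labels = labels.copy()
        n = labels.size
        flip = rng.random(n) < _PERTURB_FRACTION
        labels[flip] = rng.integers(1, k_max + 1, size=int(flip.sum()))
        labels = Partition.compact(labels)
    state = SearchState.from_partition(snp, Partition(labels, k_max), rng=rng)
    dist = snp_hamming_distances(snp)
    while True:
        before = state.log_ml
        sweep_reassign_individuals(state)
        sweep_merge_clusters(state)
        sweep_split_relocate(state, dist)
        if state.log_ml <= before + IMPROVEMENT_TOL:
            break
    return Partition.compact(state.labels), state.log_ml


def greedy_search(
    snp: SnpMatrix,
    k_max: int,
    seed: int = 42,
    n_restarts: int = 3,
    workers: int = 1,
) -> tuple[Partition, float]:
    """Search for the partition maximising the log marginal likelihood.

    Restart *r* is seeded with ``seed + r``; restart 0 starts from the
    complete-linkage cut at ``k_max``, later restarts from rng-perturbed
    copies of it.  Restarts are independent, so they may run on several
    workers; results are reduced in restart order and the output is
    identical for any worker count.  Ties in the final score go to the
    earliest restart.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    n = snp.n_sequences
    k_max = min(k_max, n)
    if k_max == 1:
        part = Partition(labels=np.ones(n, dtype=np.int64), k_max=1)
        return part, partition_log_ml(snp, part)
    if workers > 1 and n_restarts > 1:
        outcomes = Parallel(n_jobs=workers)(
            delayed(_single_search)(snp, k_max, seed, r) for r in range(n_restarts)
        )
    else:
        outcomes = [_single_search(snp, k_max, seed, r) for r in range(n_restarts)]
    best_labels, best_lml = outcomes[0]
    for labels, lml in outcomes[1:]:
        if lml > best_lml + IMPROVEMENT_TOL:
            best_labels, best_lml = labels, lml
    return Partition(labels=best_labels, k_max=k_max), float(best_lml)
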