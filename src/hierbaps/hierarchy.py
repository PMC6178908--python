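"""Hierarchical clustering: recursive application of the partition search.

Level 1 clusters the full SNP matrix.  Each discovered cluster is then
re-clustered on its own: its sequences are extracted, the locus filter is
re-applied (within a cluster many loci become invariant and allele
inventories shrink, which changes N_A(j) and hence the hyperparameters),
and the search is re-run with ``k_max = min(n_pops, subset size)``.  A
cluster whose own search prefers a single cluster — or that is too small,
or retains no polymorphic loci — is inherited unsplit.  Labels at every
level are globally unique, assigned by ascending parent label and then
sub-cluster index, so deeper levels strictly refine shallower ones.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .alignment import NoPolymorphicLociError, SnpMatrix
from .likelihood import Partition, partition_log_ml
from .search import greedy_search

_MIN_SPLIT_SIZE = 4
_SEED_MOD = 2**31 - 1


@dataclass(frozen=True)
class LmlEntry:
    """Final log marginal likelihood of one per-cluster search.

    ``cluster`` is the (level-1-based) parent label whose members were
    searched; level 1 has a single entry with ``cluster = 0`` for the full
    data set.  Parents inherited unsplit carry the log-ML of their
    single-cluster partition on the re-filtered subset (0.0 when no
    polymorphic loci survive), so per-level entries always sum to the
    level's total log-ML over subset matrices.
    """

    level: int
    cluster: int
    log_ml: float
    searched: bool = True


@dataclass
class HierResult:
    """Nested partitions per level plus per-search log marginal likelihoods."""

    ids: tuple[str, ...]
    assignments: np.ndarray  # (n, max_depth), 1-based labels per level
    lml: list[LmlEntry]
    params: dict[str, Any] = field(default_factory=dict)

    @property
    def max_depth(self) -> int:
        return int(self.assignments.shape[1])

    def n_clusters(self, level: int) -> int:
        return int(self.assignments[:, level - 1].max())

    def to_frame(self) -> pd.DataFrame:
        """Partition table: one row per isolate, one column per level."""
        data = {"Isolate": list(self.ids)}
        for d in range(self.max_depth):
            data[f"level {d + 1}"] = self.assignments[:, d]
        return pd.DataFrame(data)

    def level_log_ml(self, level: int) -> float:
        return float(sum(e.log_ml for e in self.lml if e.level == level))


def subset_seed(seed: int, depth: int, parent: int) -> int:
    """Deterministic seed for the subset search of one parent cluster.

    Derived through a SeedSequence spawn key so it depends only on
    (seed, depth, parent), never on traversal order or worker count.
    """
    ss = np.random.SeedSequence(entropy=int(seed) % _SEED_MOD, spawn_key=(depth, parent))
    return int(ss.generate_state(1, np.uint32)[0]) % (_SEED_MOD - 1000)


def hierbaps(
    snp: SnpMatrix,
    max_depth: int = 2,
    n_pops: int = 20,
    seed: int = 42,
    n_restarts: int = 3,
    workers: int = 1,
    quiet: bool = True,
) -> HierResult:
    """Hierarchically cluster a SNP matrix.

    Parameters
    ----------
    snp
        Encoded polymorphic loci (the subset filter reuses its
        ``keep_singletons`` setting).
    max_depth
        Number of nested clustering levels (>= 1).
    n_pops
        Upper bound K_max on the number of clusters of every search.
    seed, n_restarts, workers
        Search reproducibility and effort controls; identical inputs and
        seed give identical output for any worker count.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if n_pops < 2:
        raise ValueError("n_pops must be >= 2")
    n = snp.n_sequences
    assignments = np.zeros((n, max_depth), dtype=np.int64)

    if not quiet:
        print(f"[hierbaps] level 1: clustering {n} sequences, "
              f"{snp.n_loci} loci, K_max={min(n_pops, n)}", file=sys.stderr)
    part, lml = greedy_search(snp, min(n_pops, n), seed, n_restarts, workers)
    assignments[:, 0] = part.labels
    entries = [LmlEntry(level=1, cluster=0, log_ml=lml)]

    for depth in range(2, max_depth + 1):
        prev = assignments[:, depth - 2]
        col = np.zeros(n, dtype=np.int64)
        next_label = 0
        for parent in range(1, int(prev.max()) + 1):
            members = np.flatnonzero(prev == parent)
            local, sub_lml, searched = _search_subset(
                snp, members, n_pops, seed, depth, parent, n_restarts, workers, quiet
            )
            entries.append(
                LmlEntry(level=depth, cluster=parent, log_ml=sub_lml, searched=searched)
            )
            col[members] = next_label + local
            next_label += int(local.max())
        assignments[:, depth - 1] = col

    return HierResult(
        ids=snp.ids,
        assignments=assignments,
        lml=entries,
        params={
            "max_depth": max_depth,
            "n.pops": n_pops,
            "seed": seed,
            "n_restarts": n_restarts,
            "keep_singletons": snp.keep_singletons,
        },
    )


def _search_subset(
    snp: SnpMatrix,
    members: np.ndarray,
    n_pops: int,
    seed: int,
    depth: int,
    parent: int,
    n_restarts: int,
    workers: int,
    quiet: bool,
) -> tuple[np.ndarray, float, bool]:
    """Cluster one parent's members; returns (local labels, log-ML, searched)."""
    size = members.size
    sub_snp = None
    try:
        sub_snp = snp.subset(members)
    except NoPolymorphicLociError:
        pass
    if size < _MIN_SPLIT_SIZE or sub_snp is None:
        lml = 0.0
        if sub_snp is not None:
            single = Partition(np.ones(size, dtype=np.int64), k_max=1)
            lml = partition_log_ml(sub_snp, single)
        return np.ones(size, dtype=np.int64), lml, False
    if not quiet:
        print(f"[hierbaps] level {depth}: searching cluster {parent} "
              f"({size} sequences, {sub_snp.n_loci} loci)", file=sys.stderr)
    sub_seed = subset_seed(seed, depth, parent)
    part, lml = greedy_search(
        sub_snp, min(n_pops, size), sub_seed, n_restarts, workers
    )
    return part.labels, lml, True
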