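"""Collapsed Dirichlet-multinomial likelihood of a partition.

The model: each cluster *i* has its own allele-frequency vector at every
locus *j*, with a symmetric Dirichlet prior of hyperparameter
``alpha_j = 1/N_A(j)`` per allele.  Integrating the frequencies out gives
the marginal likelihood of a partition S as a product over clusters and
loci of Dirichlet-multinomial terms

    P(data | S) = prod_i prod_j  G(sum_l a) / G(sum_l a + n_ij.)
                                 * prod_l G(a + n_ijl) / G(a)

where ``n_ijl`` is the count of allele *l* at locus *j* in cluster *i* and
G is the gamma function.  All arithmetic is in natural-log space via
log-gamma.  Because every locus has N_A(j) alleles each with hyperparameter
1/N_A(j), the per-locus hyperparameter total is exactly 1.

The prior over partitions is uniform over the number of clusters
K in {1..K_max} and flat over the partitions sharing a given K, so
``log P(S) = -log K_max - log S2(n, K)`` with S2 the Stirling number of the
second kind.  At fixed K the prior cancels from any comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import gammaln

from .alignment import MISSING, SnpMatrix

#: Minimum log-likelihood gain for a search move to count as an improvement.
IMPROVEMENT_TOL: float = 1e-10

_MAX_ALLELES = 4


@dataclass(frozen=True)
class Hyperparameters:
    """Per-locus symmetric Dirichlet hyperparameter, ``alpha[j] = 1/N_A(j)``."""

    alpha: np.ndarray

    @classmethod
    def from_snp(cls, snp: SnpMatrix) -> "Hyperparameters":
        return cls(alpha=1.0 / snp.n_alleles.astype(np.float64))


@dataclass
class Partition:
    """Assignment of each sequence to one of K clusters.

    Labels are 1-based, compacted to ``{1..K}`` in order of first
    appearance; every cluster is non-empty and ``K <= k_max <= n``.
    """

    labels: np.ndarray
    k_max: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        n = self.labels.size
        if n < 1:
            raise ValueError("partition of zero sequences")
        if not (1 <= self.k_max <= n):
            raise ValueError(f"k_max must be in [1, n={n}], got {self.k_max}")
        k = self.labels.max(initial=0)
        if self.labels.min(initial=1) < 1 or k > self.k_max:
            raise ValueError("labels must lie in {1..k_max}")
        if not np.array_equal(np.unique(self.labels), np.arange(1, k + 1)):
            raise ValueError("labels must be compacted to {1..K} with no empty cluster")

    @property
    def n(self) -> int:
        return int(self.labels.size)

    @property
    def k(self) -> int:
        return int(self.labels.max())

    @staticmethod
    def compact(labels: np.ndarray) -> np.ndarray:
        """Relabel to 1..K in order of first appearance."""
        labels = np.asarray(labels)
        out = np.empty(labels.size, dtype=np.int64)
        mapping: dict[int, int] = {}
        for i, lab in enumerate(labels):
            mapping.setdefault(int(lab), len(mapping) + 1)
            out[i] = mapping[int(lab)]
        return out


@dataclass
class AlleleCountTable:
    """Per-cluster allele counts ``n_ijl`` (K x M x 4) and cluster sizes."""

    counts: np.ndarray
    cluster_sizes: np.ndarray

    @classmethod
    def from_partition(cls, snp: SnpMatrix, part: Partition) -> "AlleleCountTable":
        if part.n != snp.n_sequences:
            raise ValueError(
                f"partition over {part.n} sequences does not match "
                f"SNP matrix with {snp.n_sequences}"
            )
        k, m = part.k, snp.n_loci
        counts = np.zeros((k, m, _MAX_ALLELES), dtype=np.int64)
        rows, cols = np.nonzero(snp.codes != MISSING)
        np.add.at(counts, (part.labels[rows] - 1, cols, snp.codes[rows, cols]), 1)
        sizes = np.bincount(part.labels - 1, minlength=k).astype(np.int64)
        return cls(counts=counts, cluster_sizes=sizes)


def cluster_locus_log_ml(counts, alpha: float) -> float:
    """Log Dirichlet-multinomial marginal likelihood of one count vector.

    *counts* are the allele counts of one cluster at one locus and *alpha*
    the (scalar, symmetric) Dirichlet hyperparameter of each allele.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 1 or counts.size < 1:
        raise ValueError("counts must be a non-empty vector")
    if np.any(counts < 0) or np.any(counts != np.floor(counts)):
        raise ValueError("counts must be non-negative integers")
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    a_tot = alpha * counts.size
    n_tot = counts.sum()
    return float(
        gammaln(a_tot)
        - gammaln(a_tot + n_tot)
        + (gammaln(alpha + counts) - gammaln(alpha)).sum()
    )


def cluster_contributions(count_block: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-cluster log-ML contributions of a ``(K, M, 4)`` count block.

    Assumes the per-locus hyperparameter total is 1 (alpha = 1/N_A(j) with
    padded allele slots holding zero counts, which contribute nothing).
    """
    block = np.atleast_3d(count_block)
    totals = block.sum(axis=-1)
    per_allele = gammaln(alpha[None, :, None] + block) - gammaln(alpha)[None, :, None]
    return (-gammaln(1.0 + totals) + per_allele.sum(axis=-1)).sum(axis=-1)


def partition_log_ml(
    snp: SnpMatrix, part: Partition, hyp: Hyperparameters | None = None
) -> float:
    """Log marginal likelihood ``log P(data | S)`` of a partition."""
    if hyp is None:
        hyp = Hyperparameters.from_snp(snp)
    table = AlleleCountTable.from_partition(snp, part)
    return float(cluster_contributions(table.counts, hyp.alpha).sum())


@lru_cache(maxsize=4096)
def log_stirling2(n: int, k: int) -> float:
    """Log of the Stirling number of the second kind, computed exactly."""
    if not (0 < k <= n):
        raise ValueError("need 0 < k <= n")
    total = 0
    for j in range(k + 1):
        term = math.comb(k, j) * (k - j) ** n
        total += -term if j % 2 else term
    s2 = total // math.factorial(k)
    return math.log(s2)


def log_posterior(
    snp: SnpMatrix, part: Partition, hyp: Hyperparameters | None = None
) -> float:
    """Unnormalised log posterior: log P(data|S) + log P(S).

    P(S) is uniform over K in {1..K_max} and flat over the partitions with
    a given K; the normalising constant over all partitions is never
    computed.
    """
    return (
        partition_log_ml(snp, part, hyp)
        - math.log(part.k_max)
        - log_stirling2(part.n, part.k)
    )


@dataclass
class SearchState:
    """A partition with cached counts and log-ML, supporting O(M) moves.

    ``history`` records the cached log-ML after every applied move; the
    greedy search only applies strict improvements, so it must be
    non-decreasing.
    """

    snp: SnpMatrix
    labels: np.ndarray
    k_max: int
    alpha: np.ndarray
    counts: np.ndarray
    cluster_sizes: np.ndarray
    cluster_log_ml: np.ndarray
    log_ml: float
    rng: np.random.Generator
    history: list = field(default_factory=list)

    @classmethod
    def from_partition(
        cls,
        snp: SnpMatrix,
        part: Partition,
        seed: int | None = None,
        rng: np.random.Generator | None = None,
    ) -> "SearchState":
        hyp = Hyperparameters.from_snp(snp)
        table = AlleleCountTable.from_partition(snp, part)
        contribs = cluster_contributions(table.counts, hyp.alpha)
        if rng is None:
            rng = np.random.default_rng(seed)
        return cls(
            snp=snp,
            labels=part.labels.copy(),
            k_max=part.k_max,
            alpha=hyp.alpha,
            counts=table.counts,
            cluster_sizes=table.cluster_sizes,
            cluster_log_ml=contribs,
            log_ml=float(contribs.sum()),
            rng=rng,
        )

    @property
    def k(self) -> int:
        return int(self.counts.shape[0])

    @property
    def partition(self) -> Partition:
        return Partition(labels=self.labels.copy(), k_max=self.k_max)

    def recompute_log_ml(self) -> float:
        """From-scratch log-ML of the current partition (for verification)."""
        return partition_log_ml(self.snp, self.partition)

    # -- observed cells of one sequence -------------------------------------
    def _observed(self, seq_index: int) -> tuple[np.ndarray, np.ndarray]:
        x = self.snp.codes[seq_index]
        loci = np.flatnonzero(x != MISSING)
        return loci, x[loci].astype(np.intp)

    def delta_add(self, seq_index: int) -> np.ndarray:
        """Log-ML gain of adding sequence *seq_index* to each existing cluster.

        The gain is the log posterior-predictive probability of the
        sequence's observed alleles under each cluster's current counts:
        sum_j log[(alpha_j + n_ij,x_j) / (1 + T_ij)].
        """
        loci, alleles = self._observed(seq_index)
        if loci.size == 0:
            return np.zeros(self.k)
        num = self.alpha[loci][None, :] + self.counts[:, loci, alleles]
        den = 1.0 + self.counts[:, loci, :].sum(axis=-1)
        return np.log(num / den).sum(axis=1)

    def delta_add_new(self, seq_index: int) -> float:
        """Log-ML gain of placing the sequence alone in a new cluster."""
        loci, _ = self._observed(seq_index)
        return float(np.log(self.alpha[loci]).sum())

    def delta_remove(self, seq_index: int) -> float:
        """Log-ML change of removing the sequence from its current cluster."""
        f = int(self.labels[seq_index]) - 1
        loci, alleles = self._observed(seq_index)
        if loci.size == 0:
            return 0.0
        num = self.alpha[loci] + self.counts[f, loci, alleles] - 1
        den = self.counts[f, loci, :].sum(axis=-1).astype(np.float64)
        return float(-np.log(num / den).sum())


def delta_log_ml_move(
    state: SearchState, seq_index: int, from_cluster: int, to_cluster: int
) -> tuple[float, bool]:
    """Exact log-ML change of moving one sequence between clusters.

    ``to_cluster`` may be ``state.k + 1`` to open a new cluster (only when
    K < K_max).  Returns ``(delta, empties_from)``; the second element
    flags that *from_cluster* would be left empty, so the caller must
    compact labels after applying the move.
    """
    if int(state.labels[seq_index]) != from_cluster:
        raise ValueError(
            f"sequence {seq_index} is in cluster {int(state.labels[seq_index])}, "
            f"not {from_cluster}"
        )
    if to_cluster == from_cluster:
        raise ValueError("to_cluster must differ from from_cluster")
    k = state.k
    if to_cluster == k + 1:
        if k >= state.k_max:
            raise ValueError("cannot open a new cluster: K = K_max")
        gain = state.delta_add_new(seq_index)
    elif 1 <= to_cluster <= k:
        gain = float(state.delta_add(seq_index)[to_cluster - 1])
    else:
        raise ValueError(f"invalid to_cluster {to_cluster} (K={k})")
    empties = int(state.cluster_sizes[from_cluster - 1]) == 1
    return state.delta_remove(seq_index) + gain, empties


def apply_move(state: SearchState, seq_index: int, to_cluster: int) -> None:
    """Move one sequence to *to_cluster* (or ``K+1`` = new), updating caches.

    Affected clusters' contributions are recomputed exactly, so the cached
    log-ML never drifts from a from-scratch evaluation.  Labels are
    compacted if the source cluster is emptied.
    """
    f = int(state.labels[seq_index]) - 1
    loci, alleles = state._observed(seq_index)
    k = state.k
    if to_cluster == k + 1:
        state.counts = np.concatenate(
            [state.counts, np.zeros((1,) + state.counts.shape[1:], dtype=np.int64)]
        )
        state.cluster_sizes = np.append(state.cluster_sizes, 0)
        state.cluster_log_ml = np.append(state.cluster_log_ml, 0.0)
    t = to_cluster - 1
    state.counts[f, loci, alleles] -= 1
    state.counts[t, loci, alleles] += 1
    state.cluster_sizes[f] -= 1
    state.cluster_sizes[t] += 1
    state.labels[seq_index] = to_cluster
    if state.cluster_sizes[f] == 0:
        state.counts = np.delete(state.counts, f, axis=0)
        state.cluster_sizes = np.delete(state.cluster_sizes, f)
        state.cluster_log_ml = np.delete(state.cluster_log_ml, f)
        state.labels[state.labels > f + 1] -= 1
        t = int(state.labels[seq_index]) - 1
        state.cluster_log_ml[t] = cluster_contributions(
            state.counts[t][None], state.alpha
        )[0]
    else:
        pair = cluster_contributions(state.counts[[f, t]], state.alpha)
        state.cluster_log_ml[f] = pair[0]
        state.cluster_log_ml[t] = pair[1]
    state.log_ml = float(state.cluster_log_ml.sum())
    state.history.append(state.log_ml)
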