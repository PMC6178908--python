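"""Model / Results interface over the hierarchical clustering engine.

`HierBAPS` holds the data and the model settings; `fit` runs the greedy
search hierarchy and returns a `HierBAPSResults` carrying the per-level
assignments, the per-search log marginal likelihoods and writers for the
standard output files.

Example
-------
>>> from hierbaps import HierBAPS, SimSpec, simulate_alignment
>>> sim = simulate_alignment(SimSpec(n_per_cluster=((20, 20), (20, 20)), seed=7))
>>> sim.write_fasta("seqs.fa")
>>> res = HierBAPS.from_fasta("seqs.fa", max_depth=2, n_pops=20).fit(seed=7)
>>> print(res.summary())
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .alignment import Alignment, SnpMatrix, encode_snp_matrix, load_fasta
from .hierarchy import HierResult, hierbaps
from .outputs import save_lml_logs, tree_annotation_table, write_partition_csv
from .simulate import adjusted_rand_index


class HierBAPS:
    """Hierarchical Dirichlet-multinomial partition model of an alignment.

    Parameters
    ----------
    snp
        Encoded SNP matrix (see :func:`hierbaps.encode_snp_matrix`).
    max_depth
        Number of nested clustering levels.
    n_pops
        Upper bound on the number of clusters at every search (K_max);
        should exceed the number of clusters expected in the data.
    """

    def __init__(self, snp: SnpMatrix, max_depth: int = 2, n_pops: int = 20):
        if max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if n_pops < 2:
            raise ValueError("n_pops must be >= 2")
        self.snp = snp
        self.max_depth = max_depth
        self.n_pops = n_pops

    @classmethod
    def from_alignment(
        cls,
        aln: Alignment,
        max_depth: int = 2,
        n_pops: int = 20,
        keep_singletons: bool = False,
    ) -> "HierBAPS":
        return cls(
            encode_snp_matrix(aln, keep_singletons=keep_singletons),
            max_depth=max_depth,
            n_pops=n_pops,
        )

    @classmethod
    def from_fasta(
        cls,
        path: str | Path,
        max_depth: int = 2,
        n_pops: int = 20,
        keep_singletons: bool = False,
    ) -> "HierBAPS":
        return cls.from_alignment(
            load_fasta(path), max_depth=max_depth, n_pops=n_pops,
            keep_singletons=keep_singletons,
        )

    def fit(
        self,
        seed: int = 42,
        n_restarts: int = 3,
        workers: int = 1,
        quiet: bool = True,
    ) -> "HierBAPSResults":
        """Run the greedy stochastic search at every level of the hierarchy."""
        result = hierbaps(
            self.snp,
            max_depth=self.max_depth,
            n_pops=self.n_pops,
            seed=seed,
            n_restarts=n_restarts,
            workers=workers,
            quiet=quiet,
        )
        return HierBAPSResults(self, result)


class HierBAPSResults:
    """Fitted hierarchy: nested assignments plus log marginal likelihoods."""

    def __init__(self, model: HierBAPS, hier: HierResult):
        self.model = model
        self.hier = hier
        #: Partition table, one row per isolate, one column per level.
        self.assignments = hier.to_frame()

    @property
    def lml_log(self):
        return self.hier.lml

    def n_clusters(self, level: int) -> int:
        return self.hier.n_clusters(level)

    def level_log_ml(self, level: int) -> float:
        """Sum of the per-search log marginal likelihoods at one level."""
        return self.hier.level_log_ml(level)

    def adjusted_rand(self, labels, level: int = 1) -> float:
        """ARI between the level's assignment and an external labeling."""
        return adjusted_rand_index(self.hier.assignments[:, level - 1], labels)

    # -- writers ------------------------------------------------------------
    def to_partition_csv(self, path: str | Path) -> Path:
        return write_partition_csv(self.hier, path)

    def save_lml_logs(self, path: str | Path) -> Path:
        return save_lml_logs(self.hier, path)

    def tree_annotation(self, newick_path: str | Path, level: int, path: str | Path) -> Path:
        return tree_annotation_table(self.hier, newick_path, level, path)

    def summary(self) -> str:
        """Human-readable account of the fitted hierarchy."""
        snp = self.model.snp
        lines = []
        rule = "=" * 64
        lines.append(rule)
        lines.append("hierBAPS results".center(64))
        lines.append(rule)
        lines.append(f"No. sequences: {snp.n_sequences:>8}    SNP loci retained: {snp.n_loci:>8}")
        lines.append(
            f"Max depth:     {self.hier.max_depth:>8}    K_max (n.pops):    {self.model.n_pops:>8}"
        )
        lines.append(
            f"Seed:          {self.hier.params.get('seed', '-'):>8}    Restarts:          "
            f"{self.hier.params.get('n_restarts', '-'):>8}"
        )
        lines.append("-" * 64)
        lines.append(f"{'Level':<8}{'Clusters':<12}{'Cluster sizes':<24}{'log ML':>18}")
        for d in range(1, self.hier.max_depth + 1):
            labels = self.hier.assignments[:, d - 1]
            sizes = np.bincount(labels)[1:]
            size_str = ",".join(map(str, sizes))
            if len(size_str) > 22:
                size_str = size_str[:19] + "..."
            lines.append(
                f"{d:<8}{self.n_clusters(d):<12}{size_str:<24}"
                f"{self.level_log_ml(d):>18.4f}"
            )
        lines.append(rule)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        ks = ", ".join(
            str(self.n_clusters(d)) for d in range(1, self.hier.max_depth + 1)
        )
        return f"<HierBAPSResults levels={self.hier.max_depth} clusters=[{ks}]>"
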