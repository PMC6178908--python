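"""Synthetic alignments with planted (optionally nested) cluster structure.

Data are generated under the clustering model's own assumptions: every
cluster owns a per-locus allele-frequency vector with a Dirichlet prior and
sequences are i.i.d. multinomial draws per locus.  A fraction ``divergence``
of loci are *structured* — each top-level cluster draws its own frequency
vector there — while the rest share one vector, so separation is tunable
from trivial to impossible.

Nested specs (a list of lists of sub-cluster sizes) add a second level by
hierarchical drift: each sub-cluster's frequencies are drawn from a
Dirichlet centred on its parent cluster's frequencies with concentration
``drift``, at every locus.  Large ``drift`` means recently diverged
subpopulations whose signal is genome-wide but weak per locus — the regime
in which sub-structure is invisible to a flat clustering of the full data
but resolvable once each top-level cluster is re-clustered on its own.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

_BASES = np.array(list("acgt"))
_MIN_SHAPE = 1e-9


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one simulated alignment.

    Parameters
    ----------
    n_per_cluster
        Cluster sizes; a flat list plants one level, a list of lists plants
        two (top-level clusters containing sub-clusters).
    n_loci
        Number of alignment columns before filtering.
    concentration
        Symmetric Dirichlet concentration of cluster allele frequencies.
        The default 0.2 keeps most loci near fixation within a cluster
        with a minor-allele-frequency spectrum concentrated near zero, the
        shape of real within-population SNP data.
    divergence
        Fraction of loci whose frequencies differ between top-level
        clusters.
    drift
        Concentration of sub-cluster frequencies around the parent's
        (nested specs only); larger = weaker sub-structure.  The default 9
        emulates recently diverged subpopulations: a genome-wide but
        per-locus weak signal.
    missing_rate
        Per-cell probability of replacing the base with ``'n'``.
    """

    n_per_cluster: tuple
    n_loci: int = 200
    concentration: float = 0.2
    divergence: float = 0.5
    drift: float = 9.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_cluster) < 1:
            raise ValueError("need at least one cluster")
        sizes = [s for grp in self._groups for s in grp]
        if any(s < 1 for s in sizes):
            raise ValueError("cluster sizes must be >= 1")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not self.concentration > 0 or not self.drift > 0:
            raise ValueError("concentration and drift must be positive")
        if not 0 <= self.divergence <= 1 or not 0 <= self.missing_rate <= 1:
            raise ValueError("divergence and missing_rate must lie in [0, 1]")

    @property
    def nested(self) -> bool:
        return any(np.ndim(x) > 0 for x in self.n_per_cluster)

    @property
    def _groups(self) -> list[list[int]]:
        if self.nested:
            return [list(np.atleast_1d(g)) for g in self.n_per_cluster]
        return [[int(s)] for s in self.n_per_cluster]

    @property
    def n_sequences(self) -> int:
        return sum(s for grp in self._groups for s in grp)


@dataclass(frozen=True)
class SimulatedAlignment:
    """Sequences plus the planted labels at each level."""

    ids: tuple[str, ...]
    sequences: tuple[str, ...]
    labels: np.ndarray  # (n, n_levels), 1-based

    @property
    def n_levels(self) -> int:
        return int(self.labels.shape[1])

    def level_labels(self, level: int) -> np.ndarray:
        return self.labels[:, level - 1]

    def write_fasta(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for name, seq in zip(self.ids, self.sequences):
                fh.write(f">{name}\n{seq}\n")
        return path

    def labels_frame(self) -> pd.DataFrame:
        data = {"Isolate": list(self.ids)}
        for d in range(self.n_levels):
            data[f"level {d + 1}"] = self.labels[:, d]
        return pd.DataFrame(data)

    def write_labels(self, path: str | Path) -> Path:
        path = Path(path)
        self.labels_frame().to_csv(path, sep="\t", index=False)
        return path


def _draw_frequencies(spec: SimSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-sub-cluster, per-locus allele frequencies, shape (n_sub, L, 4)."""
    L = spec.n_loci
    conc = spec.concentration
    structured = rng.random(L) < spec.divergence
    shared = rng.dirichlet(np.full(4, conc), size=L)  # (L, 4)
    groups = spec._groups
    top_freqs = []
    for _ in groups:
        f = shared.copy()
        n_struct = int(structured.sum())
        if n_struct:
            f[structured] = rng.dirichlet(np.full(4, conc), size=n_struct)
        top_freqs.append(f)
    freqs = []
    for g, grp in enumerate(groups):
        for _ in grp:
            if spec.nested:
                shape = np.clip(spec.drift * top_freqs[g], _MIN_SHAPE, None)
                gam = rng.gamma(shape)
                freqs.append(gam / gam.sum(axis=1, keepdims=True))
            else:
                freqs.append(top_freqs[g])
    return np.stack(freqs)


def simulate_alignment(
    spec: SimSpec,
    fasta_path: str | Path | None = None,
    labels_path: str | Path | None = None,
) -> SimulatedAlignment:
    """Generate an alignment with planted structure; deterministic in the seed.

    Optionally writes the FASTA and a labels TSV alongside returning the
    in-memory result.
    """
    rng = np.random.default_rng(spec.seed)
    freqs = _draw_frequencies(spec, rng)
    groups = spec._groups
    n = spec.n_sequences
    L = spec.n_loci

    codes = np.empty((n, L), dtype=np.int64)
    labels_top = np.empty(n, dtype=np.int64)
    labels_sub = np.empty(n, dtype=np.int64)
    row = 0
    sub_index = 0
    for g, grp in enumerate(groups):
        for size in grp:
            cum = freqs[sub_index].cumsum(axis=1)  # (L, 4)
            u = rng.random((size, L))
            # rounding can leave cum[..., -1] a hair under 1.0; clip the index
            codes[row : row + size] = np.minimum(
                (u[:, :, None] > cum[None, :, :]).sum(axis=2), 3
            )
            labels_top[row : row + size] = g + 1
            labels_sub[row : row + size] = sub_index + 1
            row += size
            sub_index += 1

    chars = _BASES[codes]
    if spec.missing_rate > 0:
        chars[rng.random((n, L)) < spec.missing_rate] = "n"
    sequences = tuple("".join(r) for r in chars)
    ids = tuple(f"seq{i + 1:04d}" for i in range(n))
    labels = (
        np.column_stack([labels_top, labels_sub])
        if spec.nested
        else labels_top[:, None]
    )
    sim = SimulatedAlignment(ids=ids, sequences=sequences, labels=labels)
    if fasta_path is not None:
        sim.write_fasta(fasta_path)
    if labels_path is not None:
        sim.write_labels(labels_path)
    return sim


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected pair-counting agreement of two labelings, in [-1, 1]."""
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if a.size != b.size:
        raise ValueError(f"label vectors differ in length: {a.size} vs {b.size}")
    return float(adjusted_rand_score(a, b))
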