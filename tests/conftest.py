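import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

import hierbaps as hb


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
    return path


def alignment_from_strings(seqs, ids=None):
    if ids is None:
        ids = [f"s{i + 1}" for i in range(len(seqs))]
    return hb.Alignment(tuple(ids), np.array([list(s) for s in seqs], dtype="<U1"))


def snp_from_columns(columns, keep_singletons=False):
    """Build a SnpMatrix from a list of per-locus character columns."""
    seqs = ["".join(col[i] for col in columns) for i in range(len(columns[0]))]
    return hb.encode_snp_matrix(
        alignment_from_strings(seqs), keep_singletons=keep_singletons
    )


def random_planted_snp(seed, n=8, n_loci=15, groups=2, keep_singletons=True):
    """Small SNP matrix with two planted groups, for oracle comparisons."""
    rng = np.random.default_rng(seed)
    sizes = [n // groups] * groups
    sizes[0] += n - sum(sizes)
    spec = hb.SimSpec(
        n_per_cluster=tuple(sizes),
        n_loci=n_loci,
        concentration=0.3,
        divergence=0.7,
        seed=int(rng.integers(2**31 - 1)),
    )
    sim = hb.simulate_alignment(spec)
    aln = alignment_from_strings(sim.sequences, sim.ids)
    return hb.encode_snp_matrix(aln, keep_singletons=keep_singletons), sim


@pytest.fixture
def twin_pairs_snp():
    """Two identical pairs differing from each other at 10 loci."""
    a = "acgtacgtac"
    b = "tgcatgcatg"
    return snp_from_columns(
        [[a[j], a[j], b[j], b[j]] for j in range(10)], keep_singletons=True
    )


@pytest.fixture
def triple_groups_snp():
    """Six sequences: two groups of identical triples."""
    a = "acgtacgtacgt"
    b = "tgcatgcatgca"
    seqs = [a] * 3 + [b] * 3
    return hb.encode_snp_matrix(alignment_from_strings(seqs), keep_singletons=True)


@pytest.fixture
def nested_sim():
    """Two macro-clusters x two sub-clusters, modest size for unit tests."""
    spec = hb.SimSpec(n_per_cluster=((12, 12), (12, 12)), n_loci=150, seed=11)
    sim = hb.simulate_alignment(spec)
    aln = alignment_from_strings(sim.sequences, sim.ids)
    return hb.encode_snp_matrix(aln), sim
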