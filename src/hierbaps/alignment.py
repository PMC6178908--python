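"""Reading alignments and encoding them as SNP matrices.

A haploid multiple sequence alignment is reduced to the polymorphic loci
that carry clustering information.  Only the four nucleotides a/c/g/t count
as alleles; gaps, ``n`` and IUPAC ambiguity codes are treated as missing
observations.  By default, loci whose minor allele is carried by a single
sequence are excluded: singleton SNPs matter for phylogenies but add noise
to a model of shared population-level allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

#: Sentinel for an unobserved (or filtered-out) cell of the SNP matrix.
MISSING: int = -1

_ALLELES = "acgt"
_N_BASES = 4


class AlignmentError(ValueError):
    """Base class for alignment input problems."""


class UnequalSequenceLengthsError(AlignmentError):
    """Sequences in the FASTA file differ in length."""


class DuplicateSequenceIdsError(AlignmentError):
    """Two or more records share an identifier."""


class TooFewSequencesError(AlignmentError):
    """Fewer than two sequences were supplied."""


class NoPolymorphicLociError(AlignmentError):
    """All alignment columns were removed by the polymorphism filter."""


@dataclass(frozen=True)
class Alignment:
    """A rectangular character alignment.

    Parameters
    ----------
    ids
        Unique sequence identifiers, in file order.
    residues
        ``(n, L)`` array of single lower-case characters.
    """

    ids: tuple[str, ...]
    residues: np.ndarray

    def __post_init__(self) -> None:
        if len(self.ids) < 2:
            raise TooFewSequencesError("an alignment needs at least 2 sequences")
        if len(set(self.ids)) != len(self.ids):
            raise DuplicateSequenceIdsError("sequence identifiers must be unique")
        if self.residues.ndim != 2 or self.residues.shape[0] != len(self.ids):
            raise AlignmentError("residues must be an (n_sequences, L) matrix")
        if self.residues.shape[1] < 1:
            raise AlignmentError("alignment length must be >= 1")

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return int(self.residues.shape[1])


def load_fasta(path: str | Path) -> Alignment:
    """Read a multi-FASTA alignment.

    Records are kept in file order; identifiers are the first
    whitespace-delimited token of each header; residues are lower-cased.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    TooFewSequencesError, UnequalSequenceLengthsError, DuplicateSequenceIdsError
        If the file does not describe a valid alignment.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such FASTA file: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise TooFewSequencesError(
            f"{path}: found {len(records)} record(s); at least 2 are required"
        )
    ids = [rec.id for rec in records]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})
        raise DuplicateSequenceIdsError(f"{path}: duplicate identifiers {dups}")
    lengths = {len(rec.seq) for rec in records}
    if len(lengths) != 1:
        raise UnequalSequenceLengthsError(
            f"{path}: sequence lengths differ ({sorted(lengths)})"
        )
    residues = np.array(
        [list(str(rec.seq).lower()) for rec in records], dtype="<U1"
    )
    return Alignment(tuple(ids), residues)


@dataclass(frozen=True)
class SnpMatrix:
    """Integer-encoded polymorphic loci of an alignment.

    ``codes[i, j]`` is the index of sequence *i*'s allele within
    ``locus_alleles[j]``, or :data:`MISSING`.  ``locus_alleles[j]`` is the
    string of distinct allele characters observed at retained locus *j*
    (major allele first); its length is N_A(j), the quantity that sets the
    Dirichlet hyperparameter 1/N_A(j) of the clustering model.
    ``source_columns`` are the 1-based positions of the retained loci in
    the original alignment.
    """

    ids: tuple[str, ...]
    codes: np.ndarray
    locus_alleles: tuple[str, ...]
    source_columns: np.ndarray
    keep_singletons: bool = False

    @property
    def n_sequences(self) -> int:
        return int(self.codes.shape[0])

    @property
    def n_loci(self) -> int:
        return int(self.codes.shape[1])

    @property
    def n_alleles(self) -> np.ndarray:
        """N_A(j): number of distinct observed alleles per retained locus."""
        return np.array([len(a) for a in self.locus_alleles], dtype=np.int64)

    def decode(self) -> np.ndarray:
        """Characters at the retained loci; MISSING cells become ``'n'``."""
        out = np.full(self.codes.shape, "n", dtype="<U1")
        for j, alleles in enumerate(self.locus_alleles):
            col = self.codes[:, j]
            for local, ch in enumerate(alleles):
                out[col == local, j] = ch
        return out

    def subset(self, indices: Sequence[int], keep_singletons: bool | None = None) -> "SnpMatrix":
        """Restrict to a subset of sequences and re-apply the locus filter.

        Within a subset many loci become invariant and allele inventories
        shrink, so N_A(j) (and hence the model's hyperparameters) must be
        recomputed.  Raises :class:`NoPolymorphicLociError` if nothing
        polymorphic survives.
        """
        if keep_singletons is None:
            keep_singletons = self.keep_singletons
        indices = np.asarray(indices, dtype=np.intp)
        sub = self.codes[indices]
        base = np.full(sub.shape, MISSING, dtype=np.int8)
        for j, alleles in enumerate(self.locus_alleles):
            col = sub[:, j]
            for local, ch in enumerate(alleles):
                base[col == local, j] = _ALLELES.index(ch)
        ids = tuple(self.ids[i] for i in indices)
        return _pack_snp_matrix(ids, base, self.source_columns, keep_singletons)


def encode_snp_matrix(aln: Alignment, keep_singletons: bool = False) -> SnpMatrix:
    """Encode an alignment as a :class:`SnpMatrix`.

    Columns with fewer than two distinct observed alleles are dropped.
    With ``keep_singletons=False`` (default) a locus is retained only if at
    least two of its alleles are each carried by >= 2 sequences, and any
    allele observed exactly once at a retained locus is recoded MISSING;
    N_A(j) is computed after this recoding.
    """
    chars = aln.residues
    base = np.full(chars.shape, MISSING, dtype=np.int8)
    for k, ch in enumerate(_ALLELES):
        base[chars == ch] = k
    source = np.arange(1, aln.length + 1, dtype=np.int64)
    return _pack_snp_matrix(aln.ids, base, source, keep_singletons)


def _pack_snp_matrix(
    ids: tuple[str, ...],
    base: np.ndarray,
    source_columns: np.ndarray,
    keep_singletons: bool,
) -> SnpMatrix:
    """Filter columns of a base-encoded (acgt-index / MISSING) matrix."""
    n, L = base.shape
    counts = np.stack([(base == k).sum(axis=0) for k in range(_N_BASES)])  # (4, L)

    kept_codes: list[np.ndarray] = []
    kept_alleles: list[str] = []
    kept_source: list[int] = []
    for j in range(L):
        cnt = counts[:, j]
        min_copies = 1 if keep_singletons else 2
        present = np.flatnonzero(cnt >= min_copies)
        if present.size < 2:
            continue
        # major allele first; ties broken alphabetically (= base index)
        order = present[np.lexsort((present, -cnt[present]))]
        remap = np.full(_N_BASES + 1, MISSING, dtype=np.int8)  # [-1] stays MISSING
        for local, k in enumerate(order):
            remap[k] = local
        kept_codes.append(remap[base[:, j]])
        kept_alleles.append("".join(_ALLELES[k] for k in order))
        kept_source.append(int(source_columns[j]))

    if not kept_codes:
        raise NoPolymorphicLociError(
            "no polymorphic loci survive filtering: every column is invariant, "
            "fully missing, or (with the default filter) has its minor allele in "
            "only one sequence; pass keep_singletons=True to relax the filter"
        )
    codes = np.column_stack(kept_codes).astype(np.int8)
    return SnpMatrix(
        ids=tuple(ids),
        codes=codes,
        locus_alleles=tuple(kept_alleles),
        source_columns=np.asarray(kept_source, dtype=np.int64),
        keep_singletons=keep_singletons,
    )
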