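"""Writers for partition tables, log-ML logs, tree annotation, and the pipeline.

All files are plain text and fully determined by the input bytes and the
run configuration; progress goes to standard error so the outputs compose
in shell pipelines.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from pathlib import Path

import dendropy
import pandas as pd

from .alignment import AlignmentError, encode_snp_matrix, load_fasta
from .hierarchy import HierResult, hierbaps


class TipMismatchError(ValueError):
    """Tree tips and alignment isolates are not the same set."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end run, echoed into output headers."""

    input_path: str
    output_prefix: str
    max_depth: int = 2
    n_pops: int = 20
    seed: int = 42
    n_restarts: int = 3
    keep_singletons: bool = False
    workers: int = 1
    tree_path: str | None = None
    level: int = 1
    quiet: bool = False


def write_partition_csv(result: HierResult, path: str | Path) -> Path:
    """CSV with header ``Isolate,level 1,...``; one row per input sequence."""
    path = Path(path)
    result.to_frame().to_csv(path, index=False)
    return path


def save_lml_logs(result: HierResult, path: str | Path) -> Path:
    """Per-level, per-search final log marginal likelihoods, full precision."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# hierBAPS log marginal likelihoods\n")
        params = " ".join(f"{k}={v}" for k, v in result.params.items())
        fh.write(f"# params: {params}\n")
        for entry in result.lml:
            tag = "searched" if entry.searched else "inherited"
            fh.write(
                f"level {entry.level}\tcluster {entry.cluster}\t{tag}\t"
                f"log_ml {entry.log_ml:.17e}\n"
            )
    return path


def read_lml_logs(path: str | Path) -> pd.DataFrame:
    """Parse a :func:`save_lml_logs` file back into a table."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        lvl, clu, tag, lml = line.split("\t")
        rows.append(
            {
                "level": int(lvl.split()[1]),
                "cluster": int(clu.split()[1]),
                "searched": tag == "searched",
                "log_ml": float(lml.split()[1]),
            }
        )
    return pd.DataFrame(rows)


def tree_annotation_table(
    result: HierResult, newick_path: str | Path, level: int, path: str | Path
) -> Path:
    """TSV mapping every tree tip to its cluster at *level*.

    The tree's tip labels and the alignment's isolates must coincide as
    sets; any symmetric difference is reported in the error.
    """
    if not 1 <= level <= result.max_depth:
        raise ValueError(f"level must be in [1, {result.max_depth}], got {level}")
    tree = dendropy.Tree.get(
        path=str(newick_path), schema="newick", preserve_underscores=True
    )
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    tip_set, iso_set = set(tips), set(result.ids)
    if tip_set != iso_set:
        extra = sorted(tip_set - iso_set)
        missing = sorted(iso_set - tip_set)
        raise TipMismatchError(
            f"tree tips and isolates differ; only in tree: {extra}; "
            f"only in alignment: {missing}"
        )
    lookup = dict(zip(result.ids, result.assignments[:, level - 1]))
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"isolate\tlevel {level}\n")
        for tip in tips:
            fh.write(f"{tip}\t{lookup[tip]}\n")
    return path


def run_pipeline(config: RunConfig) -> int:
    """Load, filter, cluster and write all outputs; returns an exit status."""
    try:
        aln = load_fasta(config.input_path)
        snp = encode_snp_matrix(aln, keep_singletons=config.keep_singletons)
        if not config.quiet:
            print(
                f"[hierbaps] {aln.n_sequences} sequences, {aln.length} columns, "
                f"{snp.n_loci} polymorphic loci retained",
                file=sys.stderr,
            )
        result = hierbaps(
            snp,
            max_depth=config.max_depth,
            n_pops=config.n_pops,
            seed=config.seed,
            n_restarts=config.n_restarts,
            workers=config.workers,
            quiet=config.quiet,
        )
        # workers is deliberately not echoed: it never affects results, and
        # output bytes must be identical for any worker count
        result.params["input"] = str(config.input_path)
        prefix = config.output_prefix
        write_partition_csv(result, f"{prefix}_partition.csv")
        save_lml_logs(result, f"{prefix}_logML.txt")
        if config.tree_path is not None:
            tree_annotation_table(
                result,
                config.tree_path,
                config.level,
                f"{prefix}_level{config.level}_annotation.tsv",
            )
        if not config.quiet:
            for d in range(1, result.max_depth + 1):
                print(
                    f"[hierbaps] level {d}: {result.n_clusters(d)} clusters",
                    file=sys.stderr,
                )
        return 0
    except (OSError, AlignmentError, ValueError) as exc:
        print(f"error: {exc}", file=sys.stderr)
        return 1
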