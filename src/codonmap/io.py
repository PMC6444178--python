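"""Readers and writers for the plain-text formats codonmap touches.

FASTA parsing is delegated to Biopython; trees are scikit-bio TreeNode
objects serialized as Newick; signals, distance matrices and reports go
through tab-separated files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import DistanceMatrix, TreeNode

from .exceptions import CodonMapError
from .maps import Signal

__all__ = [
    "SequenceRecord",
    "read_fasta",
    "write_fasta",
    "write_signal_tsv",
    "read_signal_tsv",
    "write_distance_matrix",
    "read_distance_matrix",
    "read_newick",
    "write_newick",
]


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record: identifier, free-text description, sequence."""

    id: str
    description: str
    sequence: str


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file into records; identifiers must be unique."""
    path = Path(path)
    records = [
        SequenceRecord(rec.id, rec.description, str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise CodonMapError(f"{path}: no FASTA records found")
    ids = [r.id for r in records]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise CodonMapError(f"{path}: duplicate sequence identifiers {sorted(dupes)}")
    return records


def write_fasta(records: Iterable[SequenceRecord] | Mapping[str, str], path: str | Path) -> None:
    """Write records (or an id -> sequence mapping) as FASTA, 70-column wrap."""
    if isinstance(records, Mapping):
        records = [SequenceRecord(k, k, v) for k, v in records.items()]
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.description or rec.id}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")


def write_signal_tsv(signals: Mapping[str, Signal], path: str | Path) -> None:
    """Write signals as TSV rows of (id, 1-based position, value)."""
    levels = {s.level for s in signals.values()}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# level: {', '.join(sorted(levels)) if levels else 'none'}\n")
        fh.write("id\tposition\tvalue\n")
        for seq_id, signal in signals.items():
            for pos, value in enumerate(signal.values, start=1):
                fh.write(f"{seq_id}\t{pos}\t{int(value)}\n")


def read_signal_tsv(path: str | Path) -> dict[str, Signal]:
    """Inverse of :func:`write_signal_tsv`."""
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        level = first.partition("level:")[2].strip() if first.startswith("#") else ""
    df = pd.read_csv(path, sep="\t", comment="#")
    level = level or "codon"
    out: dict[str, Signal] = {}
    for seq_id, group in df.groupby("id", sort=False):
        values = group.sort_values("position")["value"].to_numpy()
        out[str(seq_id)] = Signal(values, level)
    return out


def write_distance_matrix(dm: DistanceMatrix, path: str | Path, phylip: bool = False) -> None:
    """Write a distance matrix as TSV (or PHYLIP square format)."""
    if phylip:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(dm.ids)}\n")
            for i, taxon in enumerate(dm.ids):
                row = " ".join(f"{v:.10g}" for v in dm.data[i])
                fh.write(f"{taxon}  {row}\n")
    else:
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Read a TSV distance matrix with a header row/column of taxa."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=[str(i) for i in df.index])


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")
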