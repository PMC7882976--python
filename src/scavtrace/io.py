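"""Readers and writers for the plain-text formats the pipeline touches.

ASV tables travel as a TSV count matrix (samples in rows, header row of ASV
ids) with a sidecar metadata TSV; sequences as FASTA; trees as Newick.
Everything is kept human-auditable — no binary formats.
"""

from __future__ import annotations

import os
from collections.abc import Mapping, Iterator

import pandas as pd
import skbio
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .table import METADATA_COLUMNS, AsvTable

__all__ = [
    "SequenceSet",
    "load_asv_table",
    "write_asv_table",
    "load_fasta",
    "write_fasta",
    "load_newick",
    "write_newick",
]

_ALPHABET = set("ACGTN")


class SequenceSet(Mapping):
    """An ordered id -> nucleotide-sequence mapping with validation.

    Sequences are upper-case strings over {A,C,G,T,N}; N is permitted on
    input and never counts as identical during alignment.  Lengths must
    fall within ``length_band`` (default 300-500 nt, the scale of a 16S
    V3-V5 amplicon); pass ``length_band=None`` to skip the check.
    """

    DEFAULT_LENGTH_BAND = (300, 500)

    def __init__(self, sequences: Mapping[str, str], length_band=DEFAULT_LENGTH_BAND):
        data: dict[str, str] = {}
        for asv_id, seq in sequences.items():
            if asv_id in data:
                raise ValueError(f"duplicate sequence id {asv_id!r}")
            seq = str(seq).upper()
            if not seq:
                raise ValueError(f"empty sequence for {asv_id!r}")
            bad = set(seq) - _ALPHABET
            if bad:
                raise ValueError(
                    f"sequence {asv_id!r} has characters outside ACGTN: {sorted(bad)}"
                )
            if length_band is not None:
                lo, hi = length_band
                if not lo <= len(seq) <= hi:
                    raise ValueError(
                        f"sequence {asv_id!r} length {len(seq)} outside [{lo}, {hi}]"
                    )
            data[asv_id] = seq
        self._data = data

    def __getitem__(self, key: str) -> str:
        return self._data[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    def __repr__(self) -> str:
        return f"SequenceSet(n={len(self)})"

    def subset(self, ids) -> "SequenceSet":
        return SequenceSet({i: self._data[i] for i in ids}, length_band=None)


# ---------------------------------------------------------------------------
# ASV tables


def load_asv_table(path, metadata_path) -> AsvTable:
    """Load a TSV count matrix plus its sidecar metadata TSV.

    The matrix file has a header row of ASV ids and a first column of
    sample ids.  The metadata file is keyed by ``sample_id`` and must
    provide ``sample_type``, ``site``, ``day`` and ``is_control``.
    Samples lacking metadata are rejected.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    for col in counts.columns:
        bad = counts[col][pd.to_numeric(counts[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(
                f"malformed numeric cell at sample {bad.index[0]!r}, ASV {col!r}: "
                f"{bad.iloc[0]!r}"
            )
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise ValueError("metadata must have a sample_id column")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    meta = meta.set_index("sample_id")
    for col in METADATA_COLUMNS:
        if col not in meta.columns:
            raise ValueError(f"metadata missing required column {col!r}")
    meta["is_control"] = meta["is_control"].map(_parse_bool)
    return AsvTable(counts, meta)


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if str(value).strip().lower() in {"1", "true", "yes"}:
        return True
    if str(value).strip().lower() in {"0", "false", "no", "", "nan"}:
        return False
    raise ValueError(f"unparseable boolean {value!r}")


def write_asv_table(table: AsvTable, path, metadata_path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="sample_id")
    meta = table.metadata.loc[:, list(METADATA_COLUMNS)].copy()
    meta["is_control"] = meta["is_control"].astype(bool).map({True: "1", False: "0"})
    meta.to_csv(metadata_path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# FASTA


def load_fasta(path, length_band=None) -> SequenceSet:
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        records[rec.id] = str(rec.seq)
    if not records:
        raise ValueError(f"no sequences in {path}")
    return SequenceSet(records, length_band=length_band)


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=asv_id, description="")
        for asv_id, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Newick


def load_newick(path, expected_leaves=None) -> skbio.TreeNode:
    """Read a Newick tree; midpoint-root it if it is unrooted.

    Branch lengths must be non-negative (missing lengths are treated as
    zero).  If ``expected_leaves`` is given, the tip name set must match it
    exactly; mismatches are reported with the offending identifiers.
    """
    tree = skbio.TreeNode.read(str(path))
    if len(tree.children) > 2:
        tree = tree.root_at_midpoint()
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
        if node.length < 0:
            raise ValueError(f"negative branch length at node {node.name!r}")
    names = [tip.name for tip in tree.tips()]
    if len(names) != len(set(names)):
        raise ValueError("duplicate leaf names in tree")
    if expected_leaves is not None:
        expected = set(expected_leaves)
        got = set(names)
        if expected != got:
            raise ValueError(
                f"tree leaves do not match ASV ids: missing from tree "
                f"{sorted(expected - got)}, extra in tree {sorted(got - expected)}"
            )
    return tree


def write_newick(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path))


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return str(path)
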