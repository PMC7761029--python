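"""Readers and writers for the pipeline's plain-text formats.

TSV files carry a header row with the transcript/sample id in the first
column.  FASTA is written wrapped at 60 columns via Biopython.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exprmat import CountMatrix

__all__ = [
    "read_counts",
    "write_counts",
    "read_samples",
    "write_samples",
    "read_matrix",
    "write_matrix",
    "read_fasta",
    "write_fasta",
    "read_keywords",
    "write_keywords",
    "read_json",
    "write_json",
]


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path, float_format: str | None = None) -> None:
    df.to_csv(path, sep="\t", float_format=float_format)


def read_counts(counts_path: str | Path, lengths_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index.name = None
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    lengths.index.name = None
    return CountMatrix(counts=counts.astype(int), lengths=lengths)


def write_counts(cm: CountMatrix, counts_path: str | Path, lengths_path: str | Path) -> None:
    cm.counts.rename_axis("transcript_id").to_csv(counts_path, sep="\t")
    cm.lengths.rename("length").rename_axis("transcript_id").to_csv(lengths_path, sep="\t")


def read_samples(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tissue": str})


def write_samples(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Return an id -> sequence mapping preserving file order."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_keywords(path: str | Path) -> pd.DataFrame:
    """Keyword table: one row per (transcript_id, keyword) assignment."""
    return pd.read_csv(path, sep="\t", dtype=str)


def write_keywords(keywords: pd.DataFrame, path: str | Path) -> None:
    keywords.to_csv(path, sep="\t", index=False)


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
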