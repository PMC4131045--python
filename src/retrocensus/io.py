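"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; truth sets are BED6-like TSV (0-based
half-open) with extra columns for the paired LTR intervals; count matrices are
plain TSV with elements as rows and samples as columns.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> ordered mapping id -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path, description: str = "") -> None:
    records = [SeqRecord(Seq(s), id=name, description=description) for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """FASTQ -> list of (read id, sequence); raises on malformed records."""
    out = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            out.append((rec.id, str(rec.seq).upper()))
    except ValueError as e:
        raise ValueError(f"malformed FASTQ near record {len(out) + 1}: {e}") from e
    return out


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="element")


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ValueError("count matrix contains negative entries")
    return df
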