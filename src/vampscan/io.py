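"""File I/O: FASTA via Biopython, tables via pandas CSV."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .variants import DesignError, ProteinSequence


def read_protein_fasta(path: str | Path) -> ProteinSequence:
    """First record of a protein FASTA as a ProteinSequence."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DesignError(f"no FASTA records in {path}")
    rec = records[0]
    return ProteinSequence(rec.id, str(rec.seq).upper())


def write_reads_fasta(reads: pd.DataFrame, path: str | Path) -> None:
    """Write a (read_id, sequence) frame as FASTA."""
    records = (
        SeqRecord(Seq(seq), id=str(rid), description="")
        for rid, seq in zip(reads["read_id"], reads["sequence"])
    )
    SeqIO.write(records, str(path), "fasta")


def read_reads_fasta(path: str | Path) -> pd.DataFrame:
    rows = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise DesignError(f"no FASTA records in {path}")
    return pd.DataFrame(rows, columns=["read_id", "sequence"])


def read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(path, sep=sep)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
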