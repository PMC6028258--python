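"""Small helpers for the plain-text formats the pipeline reads and writes.

FASTA goes through Biopython; BED intervals are 0-based half-open; all
tabular data is tab-separated and round-trips through pandas.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BED file (chrom, start, end[, name]); intervals 0-based half-open."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    cols = ["chrom", "start", "end", "name"][: df.shape[1]]
    df.columns = cols + [f"col{i}" for i in range(len(cols), df.shape[1])]
    return df


def write_bed(intervals: Iterable[tuple], path: str | os.PathLike) -> None:
    """Write (chrom, start, end[, name]) tuples as BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
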