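"""Plain-text format helpers: FASTA, FASTQ, GFF3 (1-based inclusive on disk,
0-based half-open in memory) and TSV round-trips used across the pipeline."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GFF_COLUMNS = ["chrom", "source", "feature", "start", "end", "score",
               "strand", "frame", "attributes"]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) reads with constant maximum quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_gff3(features: pd.DataFrame, path: str | Path) -> None:
    """Write in-memory 0-based half-open features as 1-based inclusive GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in features.iterrows():
            fh.write("\t".join([
                str(row["chrom"]), "mirpipe", str(row["feature"]),
                str(int(row["start"]) + 1), str(int(row["end"])),
                ".", str(row.get("strand", "+")), ".",
                f"ID={row['name']}",
            ]) + "\n")


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read GFF3 into the in-memory 0-based half-open feature frame."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=GFF_COLUMNS)
    df["start"] = df["start"].astype(int) - 1
    df["end"] = df["end"].astype(int)
    df["name"] = df["attributes"].str.extract(r"ID=([^;]+)")
    return df[["chrom", "start", "end", "strand", "feature", "name"]]


def write_tsv(df: pd.DataFrame, path: str | Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", index=kwargs.pop("index", False),
              float_format=kwargs.pop("float_format", "%.6g"), **kwargs)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
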