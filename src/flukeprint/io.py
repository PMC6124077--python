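"""Readers/writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; FASTQ written gzipped with a zeroed
mtime so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an ordered id -> upper-case sequence mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(path: str | Path, seqs: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _open_maybe_gz(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality) from a possibly-gzipped FASTQ file."""
    with _open_maybe_gz(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq_gz(path: str | Path, records: Iterable[tuple[str, str, str]]) -> None:
    """Write 4-line FASTQ records gzipped, reproducibly (mtime=0, no name)."""
    with open(path, "wb") as raw:
        with gzip.GzipFile(filename="", fileobj=raw, mode="wb", mtime=0) as gz:
            for title, seq, qual in records:
                gz.write(f"@{title}\n{seq}\n+\n{qual}\n".encode("ascii"))


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
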