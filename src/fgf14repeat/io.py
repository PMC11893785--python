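"""Readers and writers for the interchange formats.

FASTQ/FASTA parsing goes through Biopython's SeqIO; errors are re-raised
with the index of the offending record.  Tables are tab-separated (TSV
avoids quoting ambiguity in sequence fields), UTF-8, Unix newlines.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO


class FileFormatError(ValueError):
    """A sequence or table file is malformed."""


def _detect_format(path: Path) -> str:
    with path.open() as fh:
        first = fh.read(1)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise FileFormatError(
        f"{path}: cannot detect format from first character {first!r}"
    )


def _parse(path: Path, fmt: str) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    parser = SeqIO.parse(str(path), fmt)
    index = 0
    while True:
        try:
            rec = next(parser)
        except StopIteration:
            return records
        except ValueError as exc:
            raise FileFormatError(f"{path}: record {index}: {exc}") from exc
        records.append((rec.id, str(rec.seq).upper()))
        index += 1


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """All (id, sequence) pairs of a 4-line FASTQ file."""
    return _parse(Path(path), "fastq")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """All (id, sequence) pairs of a FASTA file (wrapped lines allowed)."""
    return _parse(Path(path), "fasta")


def read_seqs(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA or FASTQ, auto-detected from the first character."""
    path = Path(path)
    return _parse(path, _detect_format(path))


def write_fastq(
    records: Iterable[tuple[str, str]], path: str | Path, quality_char: str = "I"
) -> None:
    with Path(path).open("w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict[str, str]:
    """Sample-to-group mapping from a two-column TSV with header."""
    df = read_tsv(path)
    for col in ("sample", "group"):
        if col not in df.columns:
            raise FileFormatError(f"{path}: manifest needs a {col!r} column")
    return dict(zip(df["sample"].astype(str), df["group"].astype(str)))
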