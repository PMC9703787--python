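"""Sequence and table I/O for the pipeline.

All sequences are plain upper-case DNA strings over ``{A, C, G, T, N}``.
Parsing goes through Biopython; this module only adds the validation the
pipeline relies on (unique non-empty ids, non-empty sequences, restricted
alphabet) and a stable on-disk layout (FASTA wrapped at 70 columns).

Coordinates everywhere in the package are 0-based, half-open; emitted
interval files are BED (0-based, half-open).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGTN")

FASTA_WRAP = 70


class ParseError(ValueError):
    """Raised when a sequence file violates the pipeline's input contract."""


@dataclass(frozen=True)
class SeqRecord:
    """A named DNA sequence.

    ``sequence`` is upper-case over {A,C,G,T,N}; ``id`` is the first
    whitespace-delimited token of the header, ``description`` the rest.
    """

    id: str
    sequence: str
    description: str = ""
    quality: str | None = field(default=None, compare=False)

    def __len__(self) -> int:
        return len(self.sequence)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _validate(records: list[SeqRecord], path: str) -> list[SeqRecord]:
    seen: set[str] = set()
    for rec in records:
        if not rec.id:
            raise ParseError(f"{path}: record with empty id")
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        if not rec.sequence:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        bad = set(rec.sequence) - DNA_ALPHABET
        if bad:
            raise ParseError(
                f"{path}: record {rec.id!r} contains non-DNA characters {sorted(bad)}"
            )
    return records


def read_fasta(path: str | os.PathLike) -> list[SeqRecord]:
    """Read a FASTA file into a list of :class:`SeqRecord` (file order).

    Multi-line sequences are concatenated and case is folded to upper.
    Malformed records raise :class:`ParseError` naming the record.
    """
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id) :].strip()
            records.append(SeqRecord(rec.id, str(rec.seq).upper(), desc))
    except ValueError as exc:
        raise ParseError(f"{path}: not FASTA ({exc})") from exc
    if not records:
        # distinguish empty file from non-FASTA content
        with open(path) as fh:
            head = fh.read(1)
        if head and head != ">":
            raise ParseError(f"{path}: not FASTA (first byte {head!r})")
    return _validate(records, str(path))


def write_fasta(records: Iterable[SeqRecord], path: str | os.PathLike) -> None:
    """Write records as FASTA wrapped at 70 columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            seq = rec.sequence
            for i in range(0, len(seq), FASTA_WRAP):
                fh.write(seq[i : i + FASTA_WRAP] + "\n")


def read_fastq(path: str | os.PathLike) -> list[SeqRecord]:
    """Read a FASTQ file; qualities are kept as the raw phred string."""
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        records.append(SeqRecord(rec.id, str(rec.seq).upper(), "", qual))
    return _validate(records, str(path))


def write_fastq(records: Iterable[SeqRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.quality or "I" * len(rec.sequence)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


def read_seqs(path: str | os.PathLike) -> list[SeqRecord]:
    """Read FASTA or FASTQ, sniffing the format from the first byte."""
    with open(path) as fh:
        first = fh.read(1)
    return read_fastq(path) if first == "@" else read_fasta(path)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_bed(
    intervals: Sequence[tuple[str, int, int, str]], path: str | os.PathLike
) -> None:
    """Write (chrom, start, end, name) tuples as 4-column BED (0-based, half-open)."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
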