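"""Basic assembly statistics (contig/scaffold summaries)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io import SeqRecord


@dataclass(frozen=True)
class AssemblyStats:
    n_seqs: int
    total_len: int
    largest_len: int
    n50: int
    gc_fraction: float  # over non-N bases only
    n_gap_bases: int  # count of N


def n50(lengths: Sequence[int]) -> int:
    """Largest L such that sequences of length >= L sum to >= half the total."""
    if not lengths:
        raise ValueError("n50 of an empty assembly is undefined")
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if 2 * acc >= total:
            return length
    return min(lengths)  # unreachable


def assembly_stats(seqs: Sequence[SeqRecord]) -> AssemblyStats:
    """Summary statistics of an assembly.

    GC is computed over determined (non-N) bases; ``n_gap_bases`` counts N.
    """
    if not seqs:
        raise ValueError("assembly_stats requires a non-empty sequence list")
    lengths = [len(s) for s in seqs]
    gc = at = n_bases = 0
    for s in seqs:
        gc += s.sequence.count("G") + s.sequence.count("C")
        at += s.sequence.count("A") + s.sequence.count("T")
        n_bases += s.sequence.count("N")
    determined = gc + at
    return AssemblyStats(
        n_seqs=len(seqs),
        total_len=sum(lengths),
        largest_len=max(lengths),
        n50=n50(lengths),
        gc_fraction=gc / determined if determined else 0.0,
        n_gap_bases=n_bases,
    )
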