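"""Interspersed (non-tandem) repeat detection and repeat statistics.

A repeat family is a maximal exactly-repeated substring of the input
sequence set, counted over both strands: a unit of length >= ``min_len``
occurring at two or more genomic placements such that not all
occurrences can be extended left or right by the same base (otherwise
the longer string would be reported instead). Forward and
reverse-complement copies belong to the same family (the unit is
canonicalized to the lexicographically smaller of the two strands) and
directly adjacent copies are collapsed as tandem arrays, which are
excluded from the interspersed tier.

Detection is suffix-array based: the sequences and their reverse
complements are concatenated with unique separator symbols, maximal
repeats are exactly the left-diverse branching intervals of the
LCP-interval tree, and their suffix-array blocks give all occurrences.
Exactness makes the definition unambiguous and independently checkable
by brute force; an alignment-based mode for diverged copies is not
needed for near-identical organelle repeats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .io import SeqRecord, revcomp

_BASE_CODE = {"A": 2, "C": 3, "G": 4, "T": 5, "N": 6}

Copy = tuple[str, int, int, str]  # (seq_id, start, end, strand)


@dataclass(frozen=True)
class RepeatFamily:
    family_id: str
    unit: str  # canonical strand (min of unit, revcomp(unit))
    copies: tuple[Copy, ...]

    @property
    def unit_length(self) -> int:
        return len(self.unit)

    @property
    def copy_number(self) -> int:
        return len(self.copies)


@dataclass(frozen=True)
class RepeatParams:
    min_len: int = 24  # the fine tier; 50 for the interspersed-RE tier
    accounting_mode: Literal["union", "family_sum", "all_copies"] = "union"
    tandem_gap: int = 0

    def __post_init__(self) -> None:
        if self.min_len < 2:
            raise ValueError("min_len must be >= 2")


def suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (O(n log^2 n), numpy-vectorized)."""
    n = len(codes)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    rank = np.unique(codes, return_inverse=True)[1].astype(np.int64)
    k = 1
    order = np.argsort(rank, kind="stable")
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r1, r2 = rank[order], key2[order]
        diff = np.ones(n, dtype=bool)
        diff[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(diff) - 1
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order
        k *= 2


def lcp_array(codes: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """Kasai's algorithm; lcp[i] = LCP(suffix sa[i-1], suffix sa[i])."""
    n = len(codes)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and codes[i + h] == codes[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


_DIVERSE = -2  # left-character summary: more than one distinct value seen


def _merge(a: int | None, b: int | None) -> int | None:
    if a is None:
        return b
    if b is None:
        return a
    if a == _DIVERSE or b == _DIVERSE or a != b:
        return _DIVERSE
    return a


def _maximal_repeat_intervals(
    codes: np.ndarray, sa: np.ndarray, lcp: np.ndarray, min_len: int
) -> list[tuple[int, int, int]]:
    """Left-diverse LCP intervals with depth >= min_len as (depth, lb, rb).

    Branching LCP intervals are right-maximal by construction; tracking
    a capped summary of the characters preceding each suffix makes the
    left-maximality test O(1) per interval.
    """
    n = len(sa)

    def left_char(pos: int) -> int:
        return int(codes[pos - 1]) if pos > 0 else -1

    out: list[tuple[int, int, int]] = []
    # stack entries: [depth, left boundary, left-char summary]; each
    # entry's summary covers the suffixes sa[lb..processed-so-far]
    stack: list[list] = [[0, 0, left_char(sa[0])]]
    for i in range(1, n + 1):
        depth = int(lcp[i]) if i < n else 0
        lb = i - 1
        carried: int | None = None
        while stack and stack[-1][0] > depth:
            d, l, summ = stack.pop()
            if d >= min_len and summ == _DIVERSE:
                out.append((d, l, i - 1))
            lb = l
            carried = _merge(carried, summ)
        if stack and stack[-1][0] == depth:
            stack[-1][2] = _merge(stack[-1][2], carried)
        elif i < n:
            if carried is None:
                carried = left_char(sa[i - 1])
            stack.append([depth, lb, carried])
        if i < n:
            stack[-1][2] = _merge(stack[-1][2], left_char(sa[i]))
    return out


def _build_text(
    seqs: Sequence[SeqRecord],
) -> tuple[np.ndarray, list[tuple[str, str, int, int]]]:
    """Concatenate sequences + reverse complements with unique separators.

    Returns the code array and per-copy layout entries
    (seq_id, strand, text offset, length).
    """
    parts: list[np.ndarray] = []
    layout: list[tuple[str, str, int, int]] = []
    sep = 10
    off = 0
    lut = np.zeros(256, dtype=np.int64)
    for base, code in _BASE_CODE.items():
        lut[ord(base)] = code
    for rec in seqs:
        for strand, s in (("+", rec.sequence), ("-", revcomp(rec.sequence))):
            arr = lut[np.frombuffer(s.encode(), dtype=np.uint8)]
            parts.append(arr)
            layout.append((rec.id, strand, off, len(s)))
            off += len(s)
            parts.append(np.array([sep], dtype=np.int64))
            off += 1
            sep += 1
    return np.concatenate(parts), layout


def find_repeats(
    seqs: Sequence[SeqRecord], params: RepeatParams | None = None
) -> list[RepeatFamily]:
    """All interspersed maximal repeat families of length >= min_len.

    Families are keyed by canonical unit sequence; copies carry the
    strand of the canonical unit at each placement. Families whose
    copies all collapse into one tandem run (adjacent within
    ``tandem_gap``) are excluded.
    """
    params = params or RepeatParams()
    if sum(len(s) for s in seqs) < params.min_len:
        raise ValueError("total sequence length is below min_len")
    codes, layout = _build_text(seqs)
    sa = suffix_array(codes)
    lcp = lcp_array(codes, sa)
    intervals = _maximal_repeat_intervals(codes, sa, lcp, params.min_len)

    # decode text positions back to (seq, strand, original coordinates)
    offsets = np.array([off for _, _, off, _ in layout], dtype=np.int64)

    def decode(pos: int, m: int) -> tuple[str, int, int, str] | None:
        ci = int(np.searchsorted(offsets, pos, side="right")) - 1
        seq_id, strand, off, length = layout[ci]
        p = pos - off
        if p + m > length:
            return None  # crosses a separator (cannot happen for real repeats)
        if strand == "+":
            return seq_id, p, p + m, "+"
        return seq_id, length - (p + m), length - p, "-"

    seq_by_id = {r.id: r.sequence for r in seqs}
    families: dict[str, dict[tuple[str, int, int], str]] = {}
    for depth, lb, rb in intervals:
        start = int(sa[lb])
        occ_decoded = [decode(int(sa[i]), depth) for i in range(lb, rb + 1)]
        first = decode(start, depth)
        assert first is not None
        sid, s, e, strand = first
        unit_fwd = seq_by_id[sid][s:e] if strand == "+" else revcomp(seq_by_id[sid][s:e])
        canon = min(unit_fwd, revcomp(unit_fwd))
        fam = families.setdefault(canon, {})
        for dec in occ_decoded:
            if dec is None:
                continue
            sid, s, e, strand = dec
            genomic = seq_by_id[sid][s:e]
            fam[(sid, s, e)] = "+" if genomic == canon else "-"

    out: list[RepeatFamily] = []
    for canon in sorted(families, key=lambda u: (-len(u), u)):
        copies = sorted(
            (sid, s, e, strand) for (sid, s, e), strand in families[canon].items()
        )
        if len(copies) < 2:
            continue
        if _tandem_runs(copies, params.tandem_gap) < 2:
            continue
        out.append(
            RepeatFamily(
                family_id=f"RE{len(out) + 1:04d}", unit=canon, copies=tuple(copies)
            )
        )
    return out


def _tandem_runs(copies: Sequence[Copy], tandem_gap: int) -> int:
    """Number of copy runs after merging directly adjacent placements."""
    runs = 0
    prev: Copy | None = None
    for c in copies:
        if prev is not None and c[0] == prev[0] and c[1] - prev[2] <= tandem_gap:
            prev = c
            continue
        runs += 1
        prev = c
    return runs


def repeat_proportion(
    families: Sequence[RepeatFamily],
    seqs: Sequence[SeqRecord],
    mode: str = "union",
) -> float:
    """Fraction of the genome that is repetitive, under a stated accounting.

    ``union`` (default): length of the union of all copy intervals over
    total length — a true genomic proportion in [0, 1]. ``family_sum``:
    sum of unit lengths over total. ``all_copies``: sum of unit length
    times copy number over total.
    """
    total = sum(len(s) for s in seqs)
    if total == 0:
        raise ValueError("empty sequence set")
    if mode == "family_sum":
        return sum(f.unit_length for f in families) / total
    if mode == "all_copies":
        return sum(f.unit_length * f.copy_number for f in families) / total
    if mode != "union":
        raise ValueError(f"unknown accounting mode {mode!r}")
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for f in families:
        for sid, s, e, _strand in f.copies:
            by_seq.setdefault(sid, []).append((s, e))
    covered = 0
    for iv in by_seq.values():
        iv.sort()
        cur_s, cur_e = iv[0]
        for s, e in iv[1:]:
            if s > cur_e:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s
    return covered / total


DEFAULT_SIZE_BINS = ((50, 200), (200, 1_000), (1_000, 10_000), (10_000, None))


def repeat_summary(
    families: Sequence[RepeatFamily],
    min_len: int = 50,
    bins: Sequence[tuple[int, int | None]] = DEFAULT_SIZE_BINS,
) -> tuple[int, float, float, list[int]]:
    """(count, mean unit length, mean copy number, size histogram) for
    families with unit length >= min_len."""
    fams = [f for f in families if f.unit_length >= min_len]
    hist = [0] * len(bins)
    for f in fams:
        for bi, (lo, hi) in enumerate(bins):
            if f.unit_length >= lo and (hi is None or f.unit_length < hi):
                hist[bi] += 1
                break
    if not fams:
        return 0, 0.0, 0.0, hist
    mean_len = sum(f.unit_length for f in fams) / len(fams)
    mean_cn = sum(f.copy_number for f in fams) / len(fams)
    return len(fams), mean_len, mean_cn, hist
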