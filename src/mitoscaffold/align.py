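"""K-mer-seeded local alignment of reads against contig sets.

The aligner finds, for each read, the local alignments ("hits") of the
read against every contig on both strands: exact k-mer seeds are
collected from an index over the contigs, clustered by diagonal, and
each cluster is verified and given precise boundaries and an identity
with edlib. A read may hit the same contig at several distinct read
locations (as BLAST reports several HSPs) — that happens exactly when
the contig is a repeat the read traverses more than once — but per
location only the best-scoring hit survives.

Read coordinates in a :class:`LocalHit` are always in the read's
original orientation; ``strand`` says whether the contig matched
forward (+) or reverse-complemented (-). All intervals are 0-based,
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import edlib

from .io import SeqRecord, revcomp

DEFAULT_K = 15


@dataclass(frozen=True)
class LocalHit:
    read_id: str
    contig_id: str
    read_start: int
    read_end: int
    contig_start: int
    contig_end: int
    strand: str  # '+' or '-'
    identity: float

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start

    @property
    def contig_span(self) -> int:
        return self.contig_end - self.contig_start

    @property
    def score(self) -> float:
        return self.identity * self.contig_span


class KmerIndex:
    """Exact k-mer index over a set of contigs (forward strand only)."""

    def __init__(self, contigs: Sequence[SeqRecord], k: int = DEFAULT_K):
        self.k = k
        self.ids = [c.id for c in contigs]
        self.seqs = [c.sequence for c in contigs]
        table: dict[str, list[tuple[int, int]]] = {}
        for ti, seq in enumerate(self.seqs):
            for p in range(len(seq) - k + 1):
                table.setdefault(seq[p : p + k], []).append((ti, p))
        self.table = table


def _clusters(
    seeds: list[tuple[int, int]], band: int, max_gap: int
) -> list[list[tuple[int, int]]]:
    """Split (q, t) seeds of one contig/strand into diagonal clusters."""
    seeds = sorted(seeds, key=lambda s: (s[0] - s[1], s[0]))
    out: list[list[tuple[int, int]]] = []
    cur: list[tuple[int, int]] = []
    for q, t in seeds:
        if cur:
            pq, pt = cur[-1]
            same_band = abs((q - t) - (pq - pt)) <= band
            near = abs(q - pq) <= max_gap
            if not (same_band and near):
                out.append(cur)
                cur = []
        cur.append((q, t))
    if cur:
        out.append(cur)
    return out


def _refine(
    oriented_read: str,
    contig_seq: str,
    cluster: list[tuple[int, int]],
    k: int,
    min_identity: float,
    pad: int = 150,
) -> tuple[int, int, int, int, float] | None:
    """Verify a seed cluster with edlib; returns oriented-read/contig
    intervals and identity, or None when no alignment is found."""
    qs = min(q for q, _ in cluster)
    qe = max(q for q, _ in cluster) + k
    ts = min(t for _, t in cluster)
    te = max(t for _, t in cluster) + k
    # extend to the natural limits of whichever sequence ends first
    d_left = min(qs, ts)
    d_right = min(len(oriented_read) - qe, len(contig_seq) - te)
    t0, t1 = ts - d_left, te + d_right
    q0, q1 = qs - d_left, qe + d_right
    pattern = contig_seq[t0:t1]
    if not pattern:
        return None
    # exact-match fast path (the common case for error-free reads)
    if oriented_read[q0:q1] == pattern:
        return q0, q1, t0, t1, 1.0
    w0 = max(0, q0 - pad)
    w1 = min(len(oriented_read), q1 + pad)
    if w1 <= w0:
        return None
    max_ed = int((1.0 - min_identity) * len(pattern)) + pad
    res = edlib.align(
        pattern, oriented_read[w0:w1], mode="HW", task="locations", k=max_ed
    )
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    loc = res["locations"][0]
    rs, re = w0 + loc[0], w0 + loc[1] + 1
    identity = 1.0 - res["editDistance"] / max(len(pattern), re - rs)
    return rs, re, t0, t1, identity


def find_local_hits(
    read: SeqRecord,
    index: KmerIndex,
    min_identity: float = 0.90,
    stride: int = 7,
    band: int = 400,
    max_seed_gap: int = 5_000,
) -> list[LocalHit]:
    """All accepted local hits of one read against the indexed contigs."""
    k = index.k
    raw: list[LocalHit] = []
    L = len(read.sequence)
    for strand, q in (("+", read.sequence), ("-", revcomp(read.sequence))):
        seeds_by_t: dict[int, list[tuple[int, int]]] = {}
        for i in range(0, max(1, len(q) - k + 1), stride):
            for ti, tp in index.table.get(q[i : i + k], ()):
                seeds_by_t.setdefault(ti, []).append((i, tp))
        for ti, seeds in seeds_by_t.items():
            for cluster in _clusters(seeds, band, max_seed_gap):
                ref = _refine(q, index.seqs[ti], cluster, k, min_identity)
                if ref is None:
                    continue
                rs, re, ts, te, identity = ref
                if identity < min_identity:
                    continue
                if strand == "-":
                    rs, re = L - re, L - rs
                raw.append(
                    LocalHit(read.id, index.ids[ti], rs, re, ts, te, strand, identity)
                )
    return _prune_overlaps(raw)


def _prune_overlaps(hits: list[LocalHit]) -> list[LocalHit]:
    """Per contig, drop hits whose read interval mostly overlaps a better one."""
    kept: list[LocalHit] = []
    by_contig: dict[str, list[LocalHit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig_id, []).append(h)
    for group in by_contig.values():
        group.sort(key=lambda h: (-h.score, h.read_start, h.strand))
        chosen: list[LocalHit] = []
        for h in group:
            clash = False
            for c in chosen:
                ov = min(h.read_end, c.read_end) - max(h.read_start, c.read_start)
                if ov > 0.5 * min(h.read_span, c.read_span):
                    clash = True
                    break
            if not clash:
                chosen.append(h)
        kept.extend(chosen)
    kept.sort(key=lambda h: (h.read_start, h.contig_id))
    return kept


def align_read_to_contigs(
    read: SeqRecord,
    contigs: Sequence[SeqRecord],
    min_identity: float = 0.90,
    index: KmerIndex | None = None,
) -> list[LocalHit]:
    """Local alignments of one read against a contig set, both strands.

    Hits below ``min_identity`` are discarded; per (read, contig,
    location) only the best hit is kept. An empty list is a valid
    result.
    """
    if index is None:
        index = KmerIndex(contigs)
    return find_local_hits(read, index, min_identity=min_identity)
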