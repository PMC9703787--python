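"""Detection of plastome-derived regions (MTPTs) in mitochondrial sequence.

Plant mitogenomes carry integrated fragments of their own plastome.
They are found here by local alignment of the plastome against the
mitochondrial sequences on both strands; hits longer than ``min_len``
with identity above ``min_identity`` are kept, and mitochondrion-side
hits that overlap or sit within ``merge_gap`` bases of each other are
merged into distinct regions. The summary proportion is the merged
region length over the total mitochondrial length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import edlib

from .align import KmerIndex, _clusters
from .io import SeqRecord, revcomp


@dataclass(frozen=True)
class MtptRegion:
    mito_id: str
    mito_start: int
    mito_end: int
    plast_start: int
    plast_end: int
    strand: str
    identity: float

    @property
    def length(self) -> int:
        return self.mito_end - self.mito_start


def _local_hits(
    plastome: SeqRecord,
    index: KmerIndex,
    min_len: int,
    min_identity: float,
    stride: int,
    band: int,
) -> list[tuple[str, int, int, int, int, str, float]]:
    """Seed-and-verify local alignments plastome vs indexed mito seqs.

    Unlike read anchoring, MTPT hits are local on *both* sides, so seed
    extents are extended only by exact base matching, never to sequence
    ends.
    """
    k = index.k
    hits = []
    L = len(plastome.sequence)
    for strand, q in (("+", plastome.sequence), ("-", revcomp(plastome.sequence))):
        seeds_by_t: dict[int, list[tuple[int, int]]] = {}
        for i in range(0, max(1, L - k + 1), stride):
            for ti, tp in index.table.get(q[i : i + k], ()):
                seeds_by_t.setdefault(ti, []).append((i, tp))
        for ti, seeds in seeds_by_t.items():
            t_seq = index.seqs[ti]
            for cluster in _clusters(seeds, band, max_gap=2 * band):
                qs = min(s[0] for s in cluster)
                qe = max(s[0] for s in cluster) + k
                ts = min(s[1] for s in cluster)
                te = max(s[1] for s in cluster) + k
                # greedy exact extension of the seed extent
                while qs > 0 and ts > 0 and q[qs - 1] == t_seq[ts - 1]:
                    qs -= 1
                    ts -= 1
                while qe < L and te < len(t_seq) and q[qe] == t_seq[te]:
                    qe += 1
                    te += 1
                if te - ts <= min_len and qe - qs <= min_len:
                    continue
                res = edlib.align(q[qs:qe], t_seq[ts:te], mode="NW")
                span = max(qe - qs, te - ts)
                identity = 1.0 - res["editDistance"] / span
                if identity <= min_identity:
                    continue
                if strand == "+":
                    ps, pe = qs, qe
                else:
                    ps, pe = L - qe, L - qs
                hits.append((index.ids[ti], ts, te, ps, pe, strand, identity))
    return hits


def find_mtpts(
    mito_seqs: Sequence[SeqRecord],
    plastome: SeqRecord,
    min_len: int = 50,
    min_identity: float = 0.90,
    merge_gap: int = 10,
    stride: int = 2,
) -> tuple[list[MtptRegion], float]:
    """Plastome-derived regions in the mitochondrial sequences.

    Returns the merged distinct regions and the fraction of the
    mitochondrial length they cover. Length and identity cutoffs are
    strict (> min_len, > min_identity).
    """
    if not mito_seqs or not plastome.sequence:
        raise ValueError("find_mtpts needs non-empty mito sequences and plastome")
    index = KmerIndex(mito_seqs)
    raw = _local_hits(plastome, index, min_len, min_identity, stride, band=60)
    raw = [h for h in raw if h[2] - h[1] > min_len]
    raw.sort(key=lambda h: (h[0], h[1], h[2]))

    regions: list[MtptRegion] = []
    cur: list[tuple[str, int, int, int, int, str, float]] = []
    for h in raw:
        if cur and h[0] == cur[-1][0] and h[1] <= max(c[2] for c in cur) + merge_gap:
            cur.append(h)
        else:
            if cur:
                regions.append(_merge_region(cur))
            cur = [h]
    if cur:
        regions.append(_merge_region(cur))
    total = sum(len(s) for s in mito_seqs)
    proportion = sum(r.length for r in regions) / total
    return regions, proportion


def _merge_region(hits: list[tuple[str, int, int, int, int, str, float]]) -> MtptRegion:
    best = max(hits, key=lambda h: (h[2] - h[1]) * h[6])
    return MtptRegion(
        mito_id=hits[0][0],
        mito_start=min(h[1] for h in hits),
        mito_end=max(h[2] for h in hits),
        plast_start=best[3],
        plast_end=best[4],
        strand=best[5],
        identity=best[6],
    )
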