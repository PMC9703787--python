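"""Seed-and-extend scaffolding of mitochondrial contigs with long reads.

The procedure mirrors manual organelle scaffolding practice, made
algorithmic:

* only long reads above a minimum length are used as framework;
* a read supports contig adjacency when it anchors both contigs — it
  covers each contig entirely or overlaps a contig terminus by a
  minimum amount — with hits collinear on the read and only a small
  gap (or overlap) between the two contig projections;
* a junction is accepted only with a minimum number of supporting
  reads (default 3);
* scaffolds grow from seeds (the longest unused non-repeat contig) in
  both directions; extension stops when a contig end has no qualifying
  partner or several conflicting ones — the alternatives land in the
  adjacency report;
* repeat-like contigs (from the coverage classifier) may be placed in
  several scaffolds; extension *through* a repeat continues only when
  reads that thread the repeat from the current flank agree on a
  unique far-side contig;
* a finished scaffold is flagged circular when its two terminal ends
  are themselves linked by enough reads;
* junction sequence between contigs is filled from the best supporting
  read (longest anchoring span), trimming bases once when the read
  shows the contigs overlapping.

Ends are written '5' and '3' for a contig's 5'- and 3'-terminus; a
junction is the unordered pair of two (contig, end) tuples, which fixes
the relative orientation of the partners without reference to any
particular scaffold strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .align import KmerIndex, LocalHit, find_local_hits
from .io import SeqRecord, revcomp
from .select import Contig

EndRef = tuple[str, str]  # (contig_id, '5' | '3')
JunctionKey = tuple[EndRef, EndRef]  # sorted pair


class ScaffoldError(ValueError):
    pass


@dataclass(frozen=True)
class ScaffoldParams:
    min_read_len: int = 10_000
    min_identity: float = 0.90
    min_end_overlap: int = 10_000
    min_support: int = 3
    small_contig_overlap_fraction: float = 0.9
    partner_min_overlap: int = 500  # weak-side terminal overlap at a junction
    end_slack: int = 50  # bp tolerance for "reaches the contig terminus"
    junction_gap: int = 1_000  # max gap/overlap between contig projections on a read
    stride: int = 7  # query k-mer sampling stride of the aligner

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")


@dataclass(frozen=True)
class Observation:
    """One read's view of one junction (fill oriented in canonical key order)."""

    read_id: str
    fill: str
    overlap: int
    anchor_span: int  # min of the two anchoring spans on the read
    total_span: int


@dataclass
class ConnectionEvidence:
    key: JunctionKey
    observations: list[Observation] = field(default_factory=list)

    @property
    def supporting_reads(self) -> list[str]:
        return sorted({o.read_id for o in self.observations})

    @property
    def support(self) -> int:
        return len({o.read_id for o in self.observations})

    @property
    def best(self) -> Observation:
        return max(
            self.observations,
            key=lambda o: (o.anchor_span, o.total_span, o.read_id),
        )


@dataclass
class ScaffoldPath:
    id: str
    placements: list[tuple[str, str, int]]  # (contig_id, orientation, start offset)
    circular: bool = False
    sequence: str = ""
    provenance: list[tuple[str, int, int]] = field(default_factory=list)  # read-derived spans

    def contig_ids(self) -> list[str]:
        return [cid for cid, _, _ in self.placements]

    def junction_end_pairs(self) -> set[frozenset]:
        """Realized adjacencies as canonical (contig, end) pairs (cf. TruthSet)."""
        pairs: set[frozenset] = set()
        order = [(cid, orient) for cid, orient, _ in self.placements]
        links = list(zip(order, order[1:]))
        if self.circular and len(order) >= 1:
            links.append((order[-1], order[0]))
        for (a, sa), (b, sb) in links:
            end_a = "3" if sa == "+" else "5"
            end_b = "5" if sb == "+" else "3"
            pairs.add(frozenset({(a, end_a), (b, end_b)}))
        return pairs


@dataclass
class ScaffoldResult:
    scaffolds: list[ScaffoldPath]
    evidence: dict[JunctionKey, ConnectionEvidence]
    adjacency_report: pd.DataFrame


def _facing(orient: str, side: str) -> str:
    """Contig end facing ``side`` ('left'/'right') for a placement orientation."""
    if side == "right":
        return "3" if orient == "+" else "5"
    return "5" if orient == "+" else "3"


def _key(a: EndRef, b: EndRef) -> JunctionKey:
    pair = sorted([a, b])
    return (pair[0], pair[1])


@dataclass
class _Chain:
    """Ordered anchored hits of one read plus per-link junction validity."""

    read_id: str
    elements: list[tuple[str, str]]  # (contig_id, strand) in read order
    valid: list[bool]


class _EvidenceIndex:
    def __init__(self) -> None:
        self.by_key: dict[JunctionKey, ConnectionEvidence] = {}
        self.partners: dict[EndRef, set[EndRef]] = {}
        self.chains: list[_Chain] = []

    def add(self, key: JunctionKey, obs: Observation) -> None:
        ev = self.by_key.setdefault(key, ConnectionEvidence(key))
        ev.observations.append(obs)
        a, b = key
        self.partners.setdefault(a, set()).add(b)
        self.partners.setdefault(b, set()).add(a)

    def support(self, a: EndRef, b: EndRef) -> int:
        ev = self.by_key.get(_key(a, b))
        return ev.support if ev else 0

    def qualified_partners(self, end: EndRef, min_support: int) -> list[tuple[EndRef, int]]:
        out = [
            (p, self.support(end, p))
            for p in self.partners.get(end, ())
        ]
        out = [(p, s) for p, s in out if s >= min_support]
        out.sort(key=lambda t: (-t[1], t[0]))
        return out


def _anchored(hit: LocalHit, contig_len: int, params: ScaffoldParams) -> bool:
    """Weak anchor: the hit reaches a contig terminus with a modest overlap.

    This is the partner-side requirement: a read selected for one
    contig identifies the adjacent contig as soon as it matches the
    partner's junction-facing terminus convincingly.
    """
    need = min(
        params.partner_min_overlap,
        params.small_contig_overlap_fraction * contig_len,
    )
    at_start = hit.contig_start <= params.end_slack
    at_end = hit.contig_end >= contig_len - params.end_slack
    return (at_start or at_end) and hit.contig_span >= need


def _strong_anchor(hit: LocalHit, contig_len: int, params: ScaffoldParams) -> bool:
    """Read-selection anchor: full contig coverage or a long terminal overlap."""
    need = min(
        params.min_end_overlap,
        params.small_contig_overlap_fraction * contig_len,
    )
    return _anchored(hit, contig_len, params) and hit.contig_span >= need


def _junction_between(
    hi: LocalHit, hj: LocalHit, lens: dict[str, int], params: ScaffoldParams
) -> tuple[EndRef, EndRef] | None:
    """Ends joined by two consecutive anchored hits on a read, if valid."""
    gap = hj.read_start - hi.read_end
    if gap > params.junction_gap or gap < -params.junction_gap:
        return None
    # at least one side must carry the strong (read-selection) anchor
    if not (
        _strong_anchor(hi, lens[hi.contig_id], params)
        or _strong_anchor(hj, lens[hj.contig_id], params)
    ):
        return None
    # the junction-facing terminus of each contig must be reached
    if hi.strand == "+":
        if hi.contig_end < lens[hi.contig_id] - params.end_slack:
            return None
        end_i = "3"
    else:
        if hi.contig_start > params.end_slack:
            return None
        end_i = "5"
    if hj.strand == "+":
        if hj.contig_start > params.end_slack:
            return None
        end_j = "5"
    else:
        if hj.contig_end < lens[hj.contig_id] - params.end_slack:
            return None
        end_j = "3"
    return (hi.contig_id, end_i), (hj.contig_id, end_j)


def collect_evidence(
    contigs: Sequence[Contig],
    long_reads: Iterable[SeqRecord],
    params: ScaffoldParams | None = None,
    index: KmerIndex | None = None,
) -> _EvidenceIndex:
    """Scan all qualifying long reads and aggregate junction evidence."""
    params = params or ScaffoldParams()
    lens = {c.id: c.length for c in contigs}
    if index is None:
        index = KmerIndex([SeqRecord(c.id, c.sequence) for c in contigs])
    ev = _EvidenceIndex()
    for read in long_reads:
        if len(read.sequence) < params.min_read_len:
            continue
        hits = find_local_hits(
            read, index, min_identity=params.min_identity, stride=params.stride
        )
        anchored = [h for h in hits if _anchored(h, lens[h.contig_id], params)]
        anchored.sort(key=lambda h: h.read_start)
        if not anchored:
            continue
        chain = _Chain(
            read.id,
            [(h.contig_id, h.strand) for h in anchored],
            [False] * (len(anchored) - 1),
        )
        for i in range(len(anchored) - 1):
            hi, hj = anchored[i], anchored[i + 1]
            ends = _junction_between(hi, hj, lens, params)
            if ends is None:
                continue
            chain.valid[i] = True
            end_a, end_b = ends
            key = _key(end_a, end_b)
            gap = hj.read_start - hi.read_end
            fill = read.sequence[hi.read_end : hj.read_start] if gap > 0 else ""
            if (end_a, end_b) != key:
                fill = revcomp(fill)
            ev.add(
                key,
                Observation(
                    read_id=read.id,
                    fill=fill,
                    overlap=max(0, -gap),
                    anchor_span=min(hi.read_span, hj.read_span),
                    total_span=hj.read_end - hi.read_start,
                ),
            )
        ev.chains.append(chain)
    return ev


def collect_connection_evidence(
    seed: Contig,
    contigs: Sequence[Contig],
    long_reads: Iterable[SeqRecord],
    params: ScaffoldParams | None = None,
) -> dict[str, list[ConnectionEvidence]]:
    """Junction evidence touching one seed contig, per seed end ('5'/'3')."""
    params = params or ScaffoldParams()
    ev = collect_evidence(contigs, long_reads, params)
    out: dict[str, list[ConnectionEvidence]] = {"5": [], "3": []}
    for end in ("5", "3"):
        for partner, _s in ev.qualified_partners((seed.id, end), 1):
            out[end].append(ev.by_key[_key((seed.id, end), partner)])
        out[end].sort(key=lambda e: -e.support)
    return out


def _match_context(
    ev: _EvidenceIndex, context: list[tuple[str, str]], min_support: int
) -> list[tuple[EndRef, str, int]]:
    """Far-side candidates for extension through a repeat, from threading reads.

    ``context`` is the scaffold-path suffix (contig, orientation) ending
    at the repeat; a read threads it when its anchored-hit chain (in
    either direction) contains the context with all junctions valid and
    continues one element further.
    """
    counts: dict[tuple[EndRef, str], set[str]] = {}
    n = len(context)
    for chain in ev.chains:
        variants = [
            (chain.elements, chain.valid),
            (
                [(c, "-" if s == "+" else "+") for c, s in reversed(chain.elements)],
                list(reversed(chain.valid)),
            ),
        ]
        for elems, valid in variants:
            for i in range(len(elems) - n):
                if elems[i : i + n] != context:
                    continue
                if not all(valid[i : i + n]):
                    continue
                nxt_contig, nxt_strand = elems[i + n]
                entering = "5" if nxt_strand == "+" else "3"
                counts.setdefault(((nxt_contig, entering), nxt_strand), set()).add(
                    chain.read_id
                )
    out = [
        (end, strand, len(reads))
        for (end, strand), reads in counts.items()
        if len(reads) >= min_support
    ]
    out.sort(key=lambda t: (-t[2], t[0]))
    return out


def adjacency_report(ev: _EvidenceIndex) -> pd.DataFrame:
    """All supported partners per contig end, sorted by support (desc)."""
    rows = []
    for end in sorted(ev.partners):
        for partner in ev.partners[end]:
            rows.append(
                {
                    "contig_id": end[0],
                    "end": end[1],
                    "partner_contig": partner[0],
                    "partner_end": partner[1],
                    "support": ev.support(end, partner),
                }
            )
    df = pd.DataFrame(
        rows, columns=["contig_id", "end", "partner_contig", "partner_end", "support"]
    )
    return df.sort_values(
        ["contig_id", "end", "support", "partner_contig"],
        ascending=[True, True, False, True],
        ignore_index=True,
    )


def _extend_right(
    path: list[tuple[str, str]],
    ev: _EvidenceIndex,
    contig_map: dict[str, Contig],
    used: set[str],
    params: ScaffoldParams,
) -> None:
    """Grow ``path`` rightward in place until no unambiguous step remains."""
    max_steps = 3 * len(contig_map) + 10
    while len(path) < max_steps:
        t_id, t_orient = path[-1]
        terminal = contig_map[t_id]
        if terminal.repeat_like:
            # context: suffix from the last non-repeat placement
            j = len(path) - 1
            while j > 0 and contig_map[path[j][0]].repeat_like:
                j -= 1
            candidates = _match_context(ev, path[j:], params.min_support)
            if len(candidates) != 1:
                return
            (next_end, next_strand, _n) = candidates[0]
            next_id = next_end[0]
            if not contig_map[next_id].repeat_like and next_id in used:
                return
            orient = "+" if next_end[1] == "5" else "-"
            path.append((next_id, orient))
            if not contig_map[next_id].repeat_like:
                used.add(next_id)
            continue
        end = (t_id, _facing(t_orient, "right"))
        partners = ev.qualified_partners(end, params.min_support)
        if not partners:
            return
        if len(partners) > 1:
            # several conflicting continuations: follow the top partner only
            # if it is a repeat (repeats legitimately take several paths and
            # get multi-placed) and clearly dominates the unique alternatives
            top, top_support = partners[0]
            others = [s for p, s in partners[1:]]
            if not (
                contig_map[top[0]].repeat_like and top_support > max(others)
            ):
                return
            partner = top
        else:
            partner = partners[0][0]
        p_id, p_end = partner
        if not contig_map[p_id].repeat_like and p_id in used:
            return  # unique contig already consumed (e.g. the far side of a circle)
        orient = "+" if p_end == "5" else "-"
        path.append((p_id, orient))
        if not contig_map[p_id].repeat_like:
            used.add(p_id)


def _flip(path: list[tuple[str, str]]) -> list[tuple[str, str]]:
    return [(cid, "-" if o == "+" else "+") for cid, o in reversed(path)]


def _is_circular(
    path: list[tuple[str, str]], ev: _EvidenceIndex, params: ScaffoldParams
) -> bool:
    right = (path[-1][0], _facing(path[-1][1], "right"))
    left = (path[0][0], _facing(path[0][1], "left"))
    if len(path) == 1 and right == left:
        return False
    return ev.support(right, left) >= params.min_support


def detect_circularity(
    scaffold: ScaffoldPath,
    contigs: Sequence[Contig],
    long_reads: Iterable[SeqRecord],
    params: ScaffoldParams | None = None,
) -> bool:
    """Do >= min_support reads link the scaffold's two terminal ends?"""
    params = params or ScaffoldParams()
    if not scaffold.placements:
        raise ScaffoldError("scaffold has no placements")
    ev = collect_evidence(contigs, long_reads, params)
    path = [(cid, orient) for cid, orient, _ in scaffold.placements]
    return _is_circular(path, ev, params)


def fill_junctions(
    path: list[tuple[str, str]],
    circular: bool,
    contig_map: dict[str, Contig],
    ev: _EvidenceIndex,
    scaffold_id: str,
) -> ScaffoldPath:
    """Assemble the scaffold sequence, junction fills taken from the best read.

    When the best read shows adjacent contigs overlapping, the
    duplicated bases are emitted once (trimmed from the incoming
    contig). The output contains no N as long as contigs and reads are
    N-free. ``provenance`` records the read-derived spans (scaffold
    coordinates) for junction-first polishing.
    """
    links: list[tuple[int, int]] = [(i, i + 1) for i in range(len(path) - 1)]
    if circular and len(path) >= 1:
        links.append((len(path) - 1, 0))

    parts: list[str] = []
    placements: list[tuple[str, str, int]] = []
    provenance: list[tuple[str, int, int]] = []
    pos = 0
    pending_trim = 0
    closing_trim = 0
    for idx, (cid, orient) in enumerate(path):
        seq = contig_map[cid].sequence
        if orient == "-":
            seq = revcomp(seq)
        if pending_trim:
            seq = seq[pending_trim:]
            pending_trim = 0
        placements.append((cid, orient, pos))
        parts.append(seq)
        pos += len(seq)
        link = [l for l in links if l[0] == idx]
        if not link:
            continue
        nxt = link[0][1]
        end_a = (cid, _facing(orient, "right"))
        n_id, n_orient = path[nxt]
        end_b = (n_id, _facing(n_orient, "left"))
        key = _key(end_a, end_b)
        evidence = ev.by_key.get(key)
        if evidence is None:
            raise ScaffoldError(
                f"junction {end_a}-{end_b} in scaffold {scaffold_id} has no spanning read"
            )
        obs = evidence.best
        fill = obs.fill if (end_a, end_b) == key else revcomp(obs.fill)
        if obs.overlap:
            if nxt == 0:
                closing_trim = obs.overlap
            else:
                pending_trim = obs.overlap
        elif fill:
            provenance.append((obs.read_id, pos, pos + len(fill)))
            parts.append(fill)
            pos += len(fill)
        else:
            provenance.append((obs.read_id, pos, pos))
    sequence = "".join(parts)
    if closing_trim:
        sequence = sequence[: len(sequence) - closing_trim]
    return ScaffoldPath(
        id=scaffold_id,
        placements=placements,
        circular=circular,
        sequence=sequence,
        provenance=provenance,
    )


def build_scaffolds(
    contigs: Sequence[Contig],
    long_reads: Iterable[SeqRecord],
    params: ScaffoldParams | None = None,
) -> ScaffoldResult:
    """Scaffold the selected contigs with long-read junction evidence.

    Seeds are processed in descending length among unused non-repeat
    contigs; every contig ends up in at least one scaffold (unconnected
    contigs become singletons), non-repeat contigs in exactly one;
    repeat-like contigs may be placed several times.
    """
    params = params or ScaffoldParams()
    for c in contigs:
        if c.copy_class is None:
            raise ScaffoldError(
                f"contig {c.id} has no copy class; run assign_copy_class first"
            )
    contig_map = {c.id: c for c in contigs}
    reads = [r for r in long_reads if len(r.sequence) >= params.min_read_len]
    ev = collect_evidence(contigs, reads, params)

    used: set[str] = set()
    placed: set[str] = set()
    scaffolds: list[ScaffoldPath] = []
    seeds = sorted(
        (c for c in contigs if not c.repeat_like),
        key=lambda c: (-c.length, c.id),
    )
    n = 0
    for seed in seeds:
        if seed.id in used:
            continue
        used.add(seed.id)
        path: list[tuple[str, str]] = [(seed.id, "+")]
        _extend_right(path, ev, contig_map, used, params)
        path = _flip(path)
        _extend_right(path, ev, contig_map, used, params)
        path = _flip(path)
        if (
            len(path) >= 3
            and path[0] == path[-1]
            and contig_map[path[0][0]].repeat_like
        ):
            # the walk went all the way around a circle and re-placed the
            # terminal repeat; drop the duplicate and close the circle
            path = path[:-1]
            circular = True
        else:
            circular = _is_circular(path, ev, params)
        n += 1
        scaffolds.append(
            fill_junctions(path, circular, contig_map, ev, f"scaffold_{n}")
        )
        placed.update(cid for cid, _ in path)

    # repeat-like contigs supported nowhere (or everything unconnected)
    for c in sorted(contigs, key=lambda c: (-c.length, c.id)):
        if c.id in placed:
            continue
        n += 1
        scaffolds.append(
            fill_junctions([(c.id, "+")], False, contig_map, ev, f"scaffold_{n}")
        )
        placed.add(c.id)

    return ScaffoldResult(
        scaffolds=scaffolds,
        evidence=ev.by_key,
        adjacency_report=adjacency_report(ev),
    )


def scaffold_records(result: ScaffoldResult) -> list[SeqRecord]:
    """Scaffold sequences as FASTA records; header carries the circular flag."""
    return [
        SeqRecord(
            s.id if not s.circular else f"{s.id}_circ",
            s.sequence,
            f"circular={'yes' if s.circular else 'no'} contigs={len(s.placements)}",
        )
        for s in result.scaffolds
    ]


def placements_table(result: ScaffoldResult, contig_map: dict[str, Contig]) -> pd.DataFrame:
    rows = []
    for s in result.scaffolds:
        for cid, orient, start in s.placements:
            rows.append(
                {
                    "scaffold": s.id,
                    "contig_id": cid,
                    "orientation": orient,
                    "start": start,
                    "end": start + contig_map[cid].length,
                    "circular": s.circular,
                }
            )
    return pd.DataFrame(rows)
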