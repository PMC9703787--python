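"""Ground-truthed simulation of multipartite plant mitogenomes.

Plant mitochondrial genomes rarely exist as one circle: they are
collections of circular and linear molecules that share interspersed
repeat families, whose copies mediate recombination and therefore
alternative segment adjacencies. This module emulates exactly that
structure so that every downstream stage (contig selection, long-read
scaffolding, polishing, repeat/MTPT detection) can be tested against a
known truth:

* unique single-copy segments and interspersed repeat families, the
  bulk of repeats 50-200 bp with a rare heavy tail >= 10 kb;
* molecules assembled from those pieces, each circular or linear, with
  an integer stoichiometry (relative cellular abundance);
* repeat-mediated alternative junctions: the same family placed between
  two different unique-segment pairs (A-R-B in one molecule, C-R-D in
  another), the pattern that shows up in real data as one
  high-coverage contig with four long-read-supported partners;
* planted plastome-derived inserts (MTPTs) at a configurable identity;
* long reads (log-normal lengths, mean ~14 kb, configurable error) and
  2 x 150 bp paired short reads at configurable depth;
* a short-read-assembler stand-in that collapses each repeat family
  into a single contig with proportionally inflated coverage.

Everything is bit-reproducible given ``SimConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SeqRecord, revcomp
from .select import Contig


class ConfigError(ValueError):
    """Raised when a simulation configuration is infeasible."""


# a few real mitochondrial genes used to label gene-carrying contigs
MITO_GENES = (
    "cox1", "cox2", "cox3", "atp1", "atp6", "atp9", "nad1", "nad2", "nad4",
    "nad5", "nad7", "cob", "ccmB", "matR", "rps3", "rps4", "rrn18", "rrn26",
)


@dataclass(frozen=True)
class RepeatLenMixture:
    """Mixture for repeat-unit lengths: bulk uniform plus a rare long tail."""

    p_bulk: float = 0.85
    bulk_range: tuple[int, int] = (50, 200)
    tail_range: tuple[int, int] = (10_000, 12_000)


@dataclass(frozen=True)
class MoleculeSpec:
    circular: bool = False
    copies: int = 1  # stoichiometry multiplier


@dataclass(frozen=True)
class MtptSpec:
    n_inserts: int = 0
    insert_len_range: tuple[int, int] = (100, 500)
    identity: float = 0.95


@dataclass(frozen=True)
class LongReadSpec:
    mean_len: float = 14_000.0
    sigma: float = 0.45  # log-normal shape
    error_rate: float = 0.0
    depth: float = 20.0
    min_len: int = 1_000


@dataclass(frozen=True)
class ShortReadSpec:
    read_len: int = 150
    insert_mean: float = 450.0
    insert_sd: float = 50.0
    depth: float = 30.0
    error_rate: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic mitogenome.

    Defaults give a ~100-300 kb multipartite genome (a scaled-down
    stand-in for the multi-megabase real thing, so suites run in
    minutes), GC 0.46, one circular and one linear molecule, and two
    interspersed repeat families of which one realizes an alternative
    junction.
    """

    seed: int = 0
    gc_target: float = 0.46
    n_unique_segments: int = 8
    unique_len_range: tuple[int, int] = (8_000, 30_000)
    n_repeat_families: int = 2
    # structural families collapse into their own contigs, so they must be
    # longer than what a short-read assembler resolves (and the 2 kb
    # selection rule); the 50-200 bp bulk of the repeat size spectrum stays
    # embedded inside unique contigs and is planted as embedded pairs below
    structural_repeat_len_range: tuple[int, int] = (2_500, 6_000)
    n_embedded_repeat_pairs: int = 4
    repeat_len_mixture: RepeatLenMixture = field(default_factory=RepeatLenMixture)
    molecules: tuple[MoleculeSpec, ...] = (
        MoleculeSpec(circular=True),
        MoleculeSpec(circular=False),
    )
    n_alt_junctions: int = 1
    repeat_placements_per_family: int = 2
    mtpt: MtptSpec = field(default_factory=MtptSpec)
    long_reads: LongReadSpec = field(default_factory=LongReadSpec)
    short_reads: ShortReadSpec = field(default_factory=ShortReadSpec)

    def validate(self) -> None:
        if self.n_unique_segments < 2 * len(self.molecules):
            raise ConfigError("need >= 2 unique segments per molecule")
        if not 0.0 <= self.gc_target <= 1.0:
            raise ConfigError("gc_target must be in [0, 1]")
        if self.n_alt_junctions > self.n_repeat_families:
            raise ConfigError("n_alt_junctions exceeds n_repeat_families")
        if self.repeat_placements_per_family < 2:
            raise ConfigError("a repeat family needs >= 2 placements")
        if not 0.0 <= self.mtpt.identity <= 1.0:
            raise ConfigError("mtpt identity must be in [0, 1]")
        for spec in self.molecules:
            if spec.copies < 1:
                raise ConfigError("molecule stoichiometry must be >= 1")
        for rate in (self.long_reads.error_rate, self.short_reads.error_rate):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError("error rates must be in [0, 1]")


@dataclass(frozen=True)
class Molecule:
    id: str
    sequence: str
    circular: bool
    copies: int

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MtptTruth:
    molecule_id: str
    start: int
    end: int
    segment_id: str
    plastome_start: int
    plastome_end: int
    strand: str
    identity: float


@dataclass(frozen=True)
class TruthSet:
    """A simulated genome plus every fact a downstream test needs.

    ``layouts`` maps molecule id to its ordered (piece id, strand)
    placements; ``molecules``, ``junction_table`` and
    ``repeat_placements`` are derived from it by :func:`_assemble`.
    Expected relative coverage normalizes a segment placed once in a
    stoichiometry-1 molecule to 1.
    """

    config: SimConfig
    segments: dict[str, str]
    repeat_units: dict[str, str]
    layouts: dict[str, tuple[bool, int, tuple[tuple[str, str], ...]]]
    molecules: tuple[Molecule, ...]
    junction_table: tuple[tuple[str, str, str, str, str], ...]
    repeat_placements: dict[str, tuple[tuple[str, int, int, str], ...]]
    mtpt_truth: tuple[MtptTruth, ...]
    contig_truth: dict[str, tuple[str, float]]
    # short repeats living inside unique segments: (unit, placements in
    # segment-local coordinates)
    embedded_repeats: tuple[tuple[str, tuple[tuple[str, int, int, str], ...]], ...] = ()

    @property
    def total_genome_len(self) -> int:
        return sum(len(m) for m in self.molecules)

    def piece_sequence(self, piece_id: str) -> str:
        return self.segments.get(piece_id) or self.repeat_units[piece_id]

    def molecule_records(self) -> list[SeqRecord]:
        return [
            SeqRecord(
                m.id,
                m.sequence,
                f"circular={'yes' if m.circular else 'no'} copies={m.copies}",
            )
            for m in self.molecules
        ]

    def repeat_proportion(self) -> float:
        """Planted repeat fraction: union of repeat placements over total length.

        Structural placements sit between unique segments and embedded
        pairs inside them, so the two tiers never overlap and their
        lengths add.
        """
        covered = sum(
            e - s for places in self.repeat_placements.values() for _, s, e, _ in places
        )
        covered += sum(
            e - s for _, places in self.embedded_repeats for _, s, e, _ in places
        )
        return covered / self.total_genome_len

    def project_segment_interval(
        self, seg_id: str, s: int, e: int, strand: str = "+"
    ) -> list[tuple[str, int, int, str]]:
        """Map a segment-local interval onto molecule coordinates."""
        out = []
        for mol_id, (_, _, layout) in self.layouts.items():
            pos = 0
            for piece_id, pstrand in layout:
                plen = len(self.piece_sequence(piece_id))
                if piece_id == seg_id:
                    if pstrand == "+":
                        out.append((mol_id, pos + s, pos + e, strand))
                    else:
                        flipped = "-" if strand == "+" else "+"
                        out.append((mol_id, pos + plen - e, pos + plen - s, flipped))
                pos += plen
        return out

    def junction_end_pairs(self) -> set[frozenset]:
        """True adjacencies as canonical (contig, end) pairs.

        Walking a molecule left to right, the junction between
        ``(A, sA)`` and ``(B, sB)`` joins A's 3' end (5' if A is
        placed reverse) to B's 5' end (3' if reverse). The unordered
        pair of (piece id, end) is orientation-neutral, so recovered
        scaffolds can be compared to truth regardless of which strand
        a scaffold was emitted on.
        """
        pairs: set[frozenset] = set()
        for a, sa, b, sb, _mol in self.junction_table:
            end_a = "3" if sa == "+" else "5"
            end_b = "5" if sb == "+" else "3"
            pairs.add(frozenset({(a, end_a), (b, end_b)}))
        return pairs


def _random_dna(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return bytes(np.frombuffer(b"ACGT", dtype=np.uint8)[idx]).decode()


def _mutate_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply substitutions at the given per-base rate (always to a different base)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _mutate_reads(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Long-read style errors: 60% substitution, 20% insertion, 20% deletion."""
    if rate <= 0:
        return seq
    out: list[str] = []
    bases = "ACGT"
    for ch in seq:
        r = rng.random()
        if r >= rate:
            out.append(ch)
            continue
        kind = rng.random()
        if kind < 0.6:  # substitution
            out.append(bases[(bases.index(ch) + rng.integers(1, 4)) % 4])
        elif kind < 0.8:  # insertion
            out.append(ch)
            out.append(bases[rng.integers(0, 4)])
        # else deletion: emit nothing
    return "".join(out)


def _rng(cfg_seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg_seed, stage)))


def _assemble(
    config: SimConfig,
    segments: dict[str, str],
    repeat_units: dict[str, str],
    layouts: dict[str, tuple[bool, int, tuple[tuple[str, str], ...]]],
    mtpt_truth: tuple[MtptTruth, ...] = (),
    embedded_repeats: tuple = (),
) -> TruthSet:
    """Derive molecules, junction table, placements and coverage truth."""
    molecules = []
    junctions: list[tuple[str, str, str, str, str]] = []
    placements: dict[str, list[tuple[str, int, int, str]]] = {
        rid: [] for rid in repeat_units
    }
    rel_cov: dict[str, float] = {pid: 0.0 for pid in (*segments, *repeat_units)}

    for mol_id, (circular, copies, layout) in layouts.items():
        parts: list[str] = []
        pos = 0
        for piece_id, strand in layout:
            seq = segments.get(piece_id)
            if seq is None:
                seq = repeat_units[piece_id]
                placements[piece_id].append((mol_id, pos, pos + len(seq), strand))
            rel_cov[piece_id] += copies
            parts.append(seq if strand == "+" else revcomp(seq))
            pos += len(seq)
        molecules.append(Molecule(mol_id, "".join(parts), circular, copies))
        for (a, sa), (b, sb) in zip(layout, layout[1:]):
            junctions.append((a, sa, b, sb, mol_id))
        if circular and len(layout) > 1:
            (a, sa), (b, sb) = layout[-1], layout[0]
            junctions.append((a, sa, b, sb, mol_id))

    contig_truth = {
        pid: ("unique" if pid in segments else "repeat", rel_cov[pid])
        for pid in (*segments, *repeat_units)
    }
    return TruthSet(
        config=config,
        segments=segments,
        repeat_units=repeat_units,
        layouts=layouts,
        molecules=tuple(molecules),
        junction_table=tuple(junctions),
        repeat_placements={k: tuple(v) for k, v in placements.items()},
        mtpt_truth=mtpt_truth,
        contig_truth=contig_truth,
        embedded_repeats=embedded_repeats,
    )


def simulate_mitogenome(config: SimConfig) -> TruthSet:
    """Draw a multipartite mitogenome satisfying ``config``.

    Unique segments are partitioned among the molecules; each repeat
    family is copied into ``repeat_placements_per_family`` junction
    slots (never two families in the same slot, so every repeat copy is
    flanked by unique sequence). The first ``n_alt_junctions`` families
    are forced onto slots with four distinct flanking segments — the
    alternative-junction (A-R-B / C-R-D) pattern.
    """
    config.validate()
    rng = _rng(config.seed, 0)

    lo, hi = config.unique_len_range
    segments = {
        f"U{i + 1}": _random_dna(int(rng.integers(lo, hi + 1)), config.gc_target, rng)
        for i in range(config.n_unique_segments)
    }

    s_lo, s_hi = config.structural_repeat_len_range
    repeat_units: dict[str, str] = {
        f"R{i + 1}": _random_dna(int(rng.integers(s_lo, s_hi + 1)), config.gc_target, rng)
        for i in range(config.n_repeat_families)
    }

    # embedded short-repeat pairs: identical copies pasted into the interior
    # of unique segments (sub-read-scale repeats a short-read assembler
    # resolves, so they never become separate contigs)
    mix = config.repeat_len_mixture
    margin = 500
    free_iv: dict[str, list[tuple[int, int]]] = {
        sid: [(margin, len(seq) - margin)]
        for sid, seq in segments.items()
        if len(seq) > 2 * margin
    }

    def take_slot(length: int) -> tuple[str, int] | None:
        choices = [
            (sid, i)
            for sid, ivs in free_iv.items()
            for i, (a, b) in enumerate(ivs)
            if b - a >= length
        ]
        if not choices:
            return None
        sid, i = choices[int(rng.integers(0, len(choices)))]
        a, b = free_iv[sid].pop(i)
        at = int(rng.integers(a, b - length + 1))
        if at - a > 0:
            free_iv[sid].append((a, at))
        if b - (at + length) > 0:
            free_iv[sid].append((at + length, b))
        return sid, at

    embedded: list[tuple[str, tuple[tuple[str, int, int, str], ...]]] = []
    for _ in range(config.n_embedded_repeat_pairs):
        # embedded copies are strictly sub-insert-size (the bulk of the
        # repeat size spectrum); anything larger would be collapsed by a
        # short-read assembler and must be a structural family instead
        unit_len = int(rng.integers(mix.bulk_range[0], mix.bulk_range[1] + 1))
        unit = _random_dna(unit_len, config.gc_target, rng)
        places = []
        for _copy in range(2):
            slot = take_slot(unit_len)
            if slot is None:
                break
            sid, at = slot
            strand = "+" if rng.random() < 0.5 else "-"
            put = unit if strand == "+" else revcomp(unit)
            seq = segments[sid]
            segments[sid] = seq[:at] + put + seq[at + unit_len :]
            places.append((sid, at, at + unit_len, strand))
        if len(places) == 2:
            embedded.append((unit, tuple(sorted(places))))

    # partition unique segments among molecules (>= 2 each)
    seg_ids = list(segments)
    rng.shuffle(seg_ids)
    n_mol = len(config.molecules)
    counts = [2] * n_mol
    for _ in range(len(seg_ids) - 2 * n_mol):
        counts[int(rng.integers(0, n_mol))] += 1
    base_layouts: list[list[tuple[str, str]]] = []
    it = iter(seg_ids)
    for c in counts:
        base_layouts.append([(next(it), "+" if rng.random() < 0.8 else "-") for _ in range(c)])

    # junction slots: (molecule index, gap index); gap i sits after segment i
    slots: list[tuple[int, int]] = []
    for mi, spec in enumerate(config.molecules):
        n_gaps = len(base_layouts[mi]) - (0 if spec.circular else 1)
        slots.extend((mi, g) for g in range(n_gaps))
    need = config.n_repeat_families * config.repeat_placements_per_family
    if need > len(slots):
        raise ConfigError(
            f"{need} repeat placements requested but only {len(slots)} junction slots exist"
        )

    def slot_flanks(slot: tuple[int, int]) -> tuple[str, str]:
        mi, g = slot
        layout = base_layouts[mi]
        return layout[g][0], layout[(g + 1) % len(layout)][0]

    free = slots.copy()
    chosen: dict[str, list[tuple[int, int]]] = {}
    for i, rid in enumerate(repeat_units):
        want = config.repeat_placements_per_family
        picked: list[tuple[int, int]] = []
        order = list(rng.permutation(len(free)))
        for j in order:
            slot = free[j]
            if i < config.n_alt_junctions:
                # alternative junction: no shared flanking segment
                used = {s for p in picked for s in slot_flanks(p)}
                if used & set(slot_flanks(slot)):
                    continue
            picked.append(slot)
            if len(picked) == want:
                break
        if len(picked) < want:
            raise ConfigError(
                f"could not find {want} disjoint junction slots for family {rid}"
            )
        for p in picked:
            free.remove(p)
        chosen[rid] = picked

    # splice repeat copies into the layouts
    inserts: dict[tuple[int, int], list[str]] = {}
    for rid, picked in chosen.items():
        for slot in picked:
            inserts.setdefault(slot, []).append(rid)
    layouts: dict[str, tuple[bool, int, tuple[tuple[str, str], ...]]] = {}
    for mi, spec in enumerate(config.molecules):
        layout: list[tuple[str, str]] = []
        for g, placed in enumerate(base_layouts[mi]):
            layout.append(placed)
            for rid in inserts.get((mi, g), []):
                layout.append((rid, "+" if rng.random() < 0.5 else "-"))
        layouts[f"m{mi + 1}"] = (spec.circular, spec.copies, tuple(layout))

    return _assemble(
        config, segments, repeat_units, layouts, (), tuple(embedded)
    )


def simulate_plastome(
    length: int = 30_000, gc: float = 0.39, seed: int = 0
) -> SeqRecord:
    """A synthetic plastome reference (stand-in for a real chloroplast genome)."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 17)))
    return SeqRecord("plastome_synthetic", _random_dna(length, gc, rng), "synthetic plastome")


def plant_mtpts(truth: TruthSet, plastome: SeqRecord, spec: MtptSpec | None = None) -> TruthSet:
    """Copy plastome windows into unique segments at the given identity.

    Each insert lands in the interior of a distinct unique segment;
    substitutions are applied so the planted copy matches the plastome
    at approximately ``spec.identity``. Returns a rebuilt TruthSet whose
    molecules, coordinates and coverage truth reflect the inserts, with
    ``mtpt_truth`` recording both coordinate systems.
    """
    spec = spec or truth.config.mtpt
    if not 0.0 <= spec.identity <= 1.0:
        raise ConfigError("mtpt identity must be in [0, 1]")
    if spec.n_inserts == 0:
        return truth
    lo, hi = spec.insert_len_range
    if hi > len(plastome):
        raise ConfigError("mtpt insert length exceeds plastome length")
    if spec.n_inserts > len(truth.segments):
        raise ConfigError("more MTPT inserts than unique segments")

    rng = _rng(truth.config.seed, 3)
    seg_ids = sorted(truth.segments)
    target_ids = [seg_ids[i] for i in rng.permutation(len(seg_ids))[: spec.n_inserts]]
    segments = dict(truth.segments)
    embedded = [
        [unit, [list(p) for p in places]] for unit, places in truth.embedded_repeats
    ]
    seg_side: list[tuple[str, int, int, int, int, str]] = []
    for seg_id in target_ids:
        ins_len = int(rng.integers(lo, hi + 1))
        seg = segments[seg_id]
        margin = max(50, min(200, len(seg) // 10))
        if len(seg) - 2 * margin <= 0:
            raise ConfigError(f"segment {seg_id} too short for an MTPT insert")
        blocked = [
            (p[1], p[2]) for _, places in embedded for p in places if p[0] == seg_id
        ]
        for _try in range(200):
            at = int(rng.integers(margin, len(seg) - margin))
            if all(not (s < at < e) for s, e in blocked):
                break
        else:
            raise ConfigError(f"no insert position free of embedded repeats in {seg_id}")
        p_start = int(rng.integers(0, len(plastome) - ins_len + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        ins = plastome.sequence[p_start : p_start + ins_len]
        if strand == "-":
            ins = revcomp(ins)
        ins = _mutate_substitutions(ins, 1.0 - spec.identity, rng)
        segments[seg_id] = seg[:at] + ins + seg[at:]
        # shift embedded-repeat coordinates downstream of the insertion
        for _, places in embedded:
            for p in places:
                if p[0] == seg_id and p[1] >= at:
                    p[1] += ins_len
                    p[2] += ins_len
        seg_side.append((seg_id, at, at + ins_len, p_start, p_start + ins_len, strand))

    rebuilt = _assemble(
        truth.config,
        segments,
        truth.repeat_units,
        truth.layouts,
        (),
        tuple((unit, tuple(tuple(p) for p in places)) for unit, places in embedded),
    )
    # project segment-local insert coordinates onto molecule coordinates
    records: list[MtptTruth] = []
    for seg_id, s, e, ps, pe, strand in seg_side:
        for mol_id, (_, _, layout) in rebuilt.layouts.items():
            pos = 0
            for piece_id, pstrand in layout:
                plen = len(rebuilt.piece_sequence(piece_id))
                if piece_id == seg_id:
                    if pstrand == "+":
                        m_s, m_e = pos + s, pos + e
                        m_strand = strand
                    else:
                        m_s, m_e = pos + plen - e, pos + plen - s
                        m_strand = "-" if strand == "+" else "+"
                    records.append(
                        MtptTruth(mol_id, m_s, m_e, seg_id, ps, pe, m_strand, spec.identity)
                    )
                pos += plen
    return replace(rebuilt, mtpt_truth=tuple(records))


def _junction_trims(truth: TruthSet, trim: int) -> dict[str, tuple[int, int]]:
    """Per piece, how many bases to trim from its (start, end) in contig
    coordinates; only junction-facing ends are trimmed, so linear
    molecule termini stay intact and short pieces keep >= half their
    length."""
    trims: dict[str, tuple[int, int]] = {}
    for mol_id, (circular, _copies, layout) in truth.layouts.items():
        for pos, (pid, strand) in enumerate(layout):
            left_is_junction = circular or pos > 0
            right_is_junction = circular or pos < len(layout) - 1
            plen = len(truth.piece_sequence(pid))
            t = min(trim, plen // 4)
            # molecule-left faces contig start when placed forward
            t_start = t if (left_is_junction if strand == "+" else right_is_junction) else 0
            t_end = t if (right_is_junction if strand == "+" else left_is_junction) else 0
            prev = trims.get(pid, (0, 0))
            trims[pid] = (max(prev[0], t_start), max(prev[1], t_end))
    return trims


def fragment_to_contigs(
    truth: TruthSet,
    base_depth: float = 89.0,
    noise_sd: float = 0.0,
    gene_hit_fraction: float = 0.5,
    junction_trim: int = 0,
) -> tuple[list[Contig], pd.DataFrame]:
    """Short-read-assembler stand-in: decompose the truth into contigs.

    One contig per unique segment and one *collapsed* contig per repeat
    family; the collapsed contig's expected coverage is the base depth
    times its total genomic copy count (weighted by stoichiometry), which
    is what a depth-of-coverage classifier must see. Gaussian
    multiplicative noise with sd ``noise_sd`` perturbs the expectation.
    A deterministic subset of unique-segment contigs is labelled with
    mitochondrial gene hits (truth labels stand in for the BLAST-vs-
    known-mitogenomes search).

    ``junction_trim`` removes up to that many bases from every
    junction-facing contig end, emulating assemblies that stop short of
    repeat boundaries; the missing bases can then only be restored from
    long-read junction fills.
    """
    rng = _rng(truth.config.seed, 5)
    contigs: list[Contig] = []
    rows = []
    trims = _junction_trims(truth, junction_trim) if junction_trim else {}
    # gene-carrying contigs include the coverage extremes: in real data the
    # gene-based selection spans low-stoichiometry and repeat contigs too
    # (gene fragments sit in repeat regions), and that span is what defines
    # the criterion-2 coverage range
    all_ids = sorted(truth.contig_truth)
    n_hits = max(1, int(round(gene_hit_fraction * len(all_ids))))
    hit_ids = {all_ids[i] for i in rng.permutation(len(all_ids))[:n_hits]}
    by_cov = sorted(all_ids, key=lambda p: truth.contig_truth[p][1])
    hit_ids.update({by_cov[0], by_cov[-1]})
    gene_pool = list(MITO_GENES)
    gi = 0
    for pid, (kind, rel) in sorted(truth.contig_truth.items()):
        seq = truth.piece_sequence(pid)
        if pid in trims:
            t_start, t_end = trims[pid]
            seq = seq[t_start : len(seq) - t_end]
        cov = base_depth * rel
        if noise_sd > 0:
            cov = max(0.1, cov * (1.0 + noise_sd * rng.standard_normal()))
        genes: list[str] = []
        if pid in hit_ids:
            genes = [gene_pool[gi % len(gene_pool)]]
            gi += 1
        contigs.append(
            Contig(id=pid, sequence=seq, mean_cov=float(cov), gene_hits=genes)
        )
        rows.append(
            {"contig_id": pid, "length": len(seq), "mean_cov": float(cov),
             "source_kind": kind, "expected_rel_cov": rel}
        )
    return contigs, pd.DataFrame(rows)


def junction_read_support(
    truth: TruthSet,
    reads: Sequence[SeqRecord],
    min_read_len: int = 10_000,
    strong_overlap: int = 10_000,
    strong_fraction: float = 0.9,
    weak_overlap: int = 500,
) -> tuple[dict[frozenset, int], dict[str, int]]:
    """Truth-side count of reads that qualify as evidence per junction.

    Uses the simulator's read provenance (molecule, start, length), not
    any alignment: a read supports a junction when it is long enough,
    covers the junction point, anchors one flanking piece with the
    strong terminal overlap (or its near-full length) and the other
    with at least the weak overlap. This is the precondition under
    which the scaffolder is expected to recover a junction; junctions
    sampled below the support threshold are structurally invisible to
    any method.

    Returns (support per canonical junction end-pair, minimum junction
    support per molecule — the bottleneck that decides whether a
    circular molecule can be closed).
    """
    # physical junctions: (canonical end pair, molecule, position, flank lengths)
    junctions: list[tuple[frozenset, str, int, int, int]] = []
    for mol_id, (circular, _copies, layout) in truth.layouts.items():
        pos = 0
        lens = [len(truth.piece_sequence(p)) for p, _ in layout]
        for i, (pid, strand) in enumerate(layout):
            pos += lens[i]
            is_last = i == len(layout) - 1
            if is_last and not circular:
                break
            nxt = layout[(i + 1) % len(layout)]
            end_a = "3" if strand == "+" else "5"
            end_b = "5" if nxt[1] == "+" else "3"
            key = frozenset({(pid, end_a), (nxt[0], end_b)})
            junctions.append(
                (key, mol_id, pos % sum(lens), lens[i], lens[(i + 1) % len(layout)])
            )
    mol_lens = {m.id: len(m) for m in truth.molecules}
    support: dict[frozenset, int] = {key: 0 for key, *_ in junctions}
    per_molecule: dict[str, int] = {}
    parsed = []
    for r in reads:
        try:
            d = dict(kv.split("=") for kv in r.description.split())
            parsed.append((d["mol"], int(d["start"]), int(d["len"])))
        except (KeyError, ValueError):
            continue
    for key, mol_id, p, len_l, len_r in junctions:
        mlen = mol_lens[mol_id]
        need_l = min(strong_overlap, strong_fraction * len_l)
        need_r = min(strong_overlap, strong_fraction * len_r)
        n = 0
        for mol, start, length in parsed:
            if mol != mol_id or length < min_read_len:
                continue
            if start <= p < start + length:
                left = p - start
            elif start <= p + mlen < start + length:
                left = p + mlen - start
            else:
                continue
            right = length - left
            span_l = min(left, len_l)
            span_r = min(right, len_r)
            strong = span_l >= need_l or span_r >= need_r
            weak = span_l >= min(weak_overlap, strong_fraction * len_l) and span_r >= min(
                weak_overlap, strong_fraction * len_r
            )
            if strong and weak:
                n += 1
        support[key] += n
        per_molecule[mol_id] = min(per_molecule.get(mol_id, 10**9), n)
    for m in truth.molecules:
        per_molecule.setdefault(m.id, 10**9)
    return support, per_molecule


def _sample_lengths(
    spec: LongReadSpec, cap: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Log-normal lengths with the requested mean, truncated to [min_len, cap]."""
    mu = math.log(spec.mean_len) - spec.sigma**2 / 2
    lens = rng.lognormal(mu, spec.sigma, size=n)
    return np.clip(lens, spec.min_len, cap).astype(int)


def simulate_long_reads(
    truth: TruthSet, spec: LongReadSpec | None = None
) -> list[SeqRecord]:
    """Sample long reads from the molecules, proportional to stoichiometry.

    Reads from circular molecules may span the origin (sampled from the
    doubled sequence). Strand is uniform; errors are applied at
    ``spec.error_rate`` (60/20/20 substitution/insertion/deletion).
    """
    spec = spec or truth.config.long_reads
    if spec.depth <= 0:
        raise ConfigError("long-read depth must be > 0")
    max_mol = max(len(m) for m in truth.molecules)
    if spec.mean_len > max_mol:
        raise ConfigError("mean read length exceeds every molecule length")
    rng = _rng(truth.config.seed, 1)
    weights = np.array([len(m) * m.copies for m in truth.molecules], dtype=float)
    weights /= weights.sum()
    target = spec.depth * sum(len(m) * m.copies for m in truth.molecules)

    reads: list[SeqRecord] = []
    total = 0
    i = 0
    while total < target:
        mol = truth.molecules[int(rng.choice(len(truth.molecules), p=weights))]
        length = int(_sample_lengths(spec, len(mol), 1, rng)[0])
        if mol.circular:
            start = int(rng.integers(0, len(mol)))
            seq = (mol.sequence + mol.sequence)[start : start + length]
        else:
            start = int(rng.integers(0, len(mol) - length + 1))
            seq = mol.sequence[start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = revcomp(seq)
        seq = _mutate_reads(seq, spec.error_rate, rng)
        reads.append(
            SeqRecord(
                f"lr{i:06d}",
                seq,
                f"mol={mol.id} start={start} len={length} strand={strand}",
            )
        )
        total += len(seq)
        i += 1
    return reads


def simulate_short_reads(
    truth: TruthSet, spec: ShortReadSpec | None = None
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Paired 2 x ``read_len`` reads from fragments of the stated insert size."""
    spec = spec or truth.config.short_reads
    if spec.depth <= 0:
        raise ConfigError("short-read depth must be > 0")
    if spec.insert_mean < 2 * spec.read_len:
        raise ConfigError("insert size must be >= twice the read length")
    genome = sum(len(m) * m.copies for m in truth.molecules)
    if genome == 0:
        raise ConfigError("empty truth set")
    rng = _rng(truth.config.seed, 2)
    weights = np.array([len(m) * m.copies for m in truth.molecules], dtype=float)
    weights /= weights.sum()
    n_pairs = int(round(spec.depth * genome / (2 * spec.read_len)))

    r1: list[SeqRecord] = []
    r2: list[SeqRecord] = []
    for i in range(n_pairs):
        mol = truth.molecules[int(rng.choice(len(truth.molecules), p=weights))]
        frag_len = int(
            np.clip(rng.normal(spec.insert_mean, spec.insert_sd),
                    2 * spec.read_len, max(2 * spec.read_len, len(mol)))
        )
        if mol.circular:
            start = int(rng.integers(0, len(mol)))
            frag = (mol.sequence + mol.sequence)[start : start + frag_len]
        else:
            if frag_len >= len(mol):
                frag_len = len(mol)
                start = 0
            else:
                start = int(rng.integers(0, len(mol) - frag_len + 1))
            frag = mol.sequence[start : start + frag_len]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        fwd = _mutate_substitutions(frag[: spec.read_len], spec.error_rate, rng)
        rev = _mutate_substitutions(
            revcomp(frag[-spec.read_len :]), spec.error_rate, rng
        )
        r1.append(SeqRecord(f"sr{i:07d}/1", fwd, ""))
        r2.append(SeqRecord(f"sr{i:07d}/2", rev, ""))
    return r1, r2
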