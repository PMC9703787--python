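"""Long-read seed-and-extend scaffolding: junction evidence, extension
rules, repeat multi-placement and circularity."""

from collections import Counter

import pytest

from mitoscaffold import (
    Contig,
    ScaffoldParams,
    SeqRecord,
    build_scaffolds,
    collect_connection_evidence,
    detect_circularity,
    revcomp,
)
from mitoscaffold.scaffold import ScaffoldError

from conftest import random_dna, scaffold_run


def _contig(cid, seq, repeat=False):
    return Contig(
        id=cid, sequence=seq, copy_class="multiple(2)" if repeat else "single",
        repeat_like=repeat, selected=True,
    )


def _windows(molecule, length, offsets, prefix="r"):
    return [
        SeqRecord(f"{prefix}{i}", molecule[o : o + length])
        for i, o in enumerate(offsets)
    ]


class TestJunctionSupport:
    A = random_dna(12000, seed=30)
    B = random_dna(12000, seed=31)
    molecule = A + B

    def test_three_supporting_reads_join_contigs(self):
        reads = _windows(self.molecule, 20000, [0, 1000, 2000])
        res = build_scaffolds([_contig("A", self.A), _contig("B", self.B)], reads)
        assert len(res.scaffolds) == 1
        assert [c for c, _, _ in res.scaffolds[0].placements] in (["A", "B"], ["B", "A"])
        assert res.scaffolds[0].sequence in (self.molecule, revcomp(self.molecule))

    def test_two_supporting_reads_do_not(self):
        reads = _windows(self.molecule, 20000, [0, 1000])
        res = build_scaffolds([_contig("A", self.A), _contig("B", self.B)], reads)
        assert len(res.scaffolds) == 2

    def test_reads_below_min_length_are_ignored(self):
        reads = _windows(self.molecule, 9000, [3000, 5000, 7000, 9000])
        res = build_scaffolds([_contig("A", self.A), _contig("B", self.B)], reads)
        assert len(res.scaffolds) == 2

    def test_per_seed_evidence_counts_and_best_read(self):
        lengths = [20000, 21000, 22000, 23000, 24000]
        reads = [
            SeqRecord(f"r{i}", self.molecule[12000 - l // 2 : 12000 + l - l // 2])
            for i, l in enumerate(lengths)
        ]
        seed = _contig("A", self.A)
        out = collect_connection_evidence(seed, [seed, _contig("B", self.B)], reads)
        (ev,) = out["3"]
        assert ev.support == 5
        assert ev.best.read_id == "r4"  # the longest spanning read
        assert out["5"] == []

    def test_missing_copy_class_is_an_error(self):
        bare = Contig(id="A", sequence=self.A)
        with pytest.raises(ScaffoldError, match="copy class"):
            build_scaffolds([bare], [])


class TestOverlapTrimming:
    def test_overlapping_contigs_emit_duplicated_bases_once(self):
        A = random_dna(12000, seed=32)
        B_tail = random_dna(11900, seed=33)
        molecule = A + B_tail
        contig_b = molecule[len(A) - 100 :]  # starts 100 bp inside A
        reads = _windows(molecule, 20000, [0, 1500, 3000])
        res = build_scaffolds([_contig("A", A), _contig("B", contig_b)], reads)
        assert len(res.scaffolds) == 1
        assert res.scaffolds[0].sequence in (molecule, revcomp(molecule))


class TestCircularity:
    def test_single_contig_circle_detected_by_origin_spanning_reads(self):
        A = random_dna(15000, seed=34)
        doubled = A + A
        # each read crosses the origin (position 15000 of the doubled
        # sequence) with >= 10 kb on one side
        reads = _windows(doubled, 12000, [3500, 4000, 4500])
        contigs = [_contig("A", A)]
        res = build_scaffolds(contigs, reads)
        assert len(res.scaffolds) == 1
        assert res.scaffolds[0].circular
        assert detect_circularity(res.scaffolds[0], contigs, reads)

    def test_linear_molecule_is_not_flagged(self):
        A = random_dna(15000, seed=35)
        reads = _windows(A, 12000, [0, 1000, 2000, 3000])
        res = build_scaffolds([_contig("A", A)], reads)
        assert not res.scaffolds[0].circular


class TestTruthRecovery:
    def test_unique_junction_molecule_recovered_exactly(self):
        """Five unique contigs of one linear molecule: one scaffold whose
        order, orientation and sequence match the truth."""
        truth, contigs, res = scaffold_run(
            seed=13,
            n_unique_segments=5,
            n_repeat_families=0,
            n_alt_junctions=0,
            n_embedded_repeat_pairs=0,
        )
        from mitoscaffold.simulate import MoleculeSpec  # noqa: F401

        found = set()
        for s in res.scaffolds:
            found |= s.junction_end_pairs()
        assert found == truth.junction_end_pairs()

    def test_alt_junction_repeat_multiplaced_with_four_partners(self, default_run):
        """The repeat family with two distinct flanking pairs lands in two
        scaffolds and its adjacency report lists four partners."""
        truth, contigs, res = default_run
        in_scaffolds = [
            s.id for s in res.scaffolds if "R1" in [c for c, _, _ in s.placements]
        ]
        assert len(in_scaffolds) >= 2
        rep = res.adjacency_report
        partners = set(rep[rep["contig_id"] == "R1"]["partner_contig"])
        assert len(partners) == 4

    def test_full_recovery_default_conditions(self, default_run):
        truth, contigs, res = default_run
        found = set()
        for s in res.scaffolds:
            found |= s.junction_end_pairs()
        truth_pairs = truth.junction_end_pairs()
        assert found == truth_pairs  # 100% recall, no false adjacencies
        assert sum(s.circular for s in res.scaffolds) == sum(
            m.circular for m in truth.molecules
        )
        for s in res.scaffolds:
            assert "N" not in s.sequence

    def test_every_contig_placed_uniques_exactly_once(self, default_run):
        truth, contigs, res = default_run
        counts = Counter(
            c for s in res.scaffolds for c, _, _ in s.placements
        )
        for c in contigs:
            assert counts[c.id] >= 1
            if not c.repeat_like:
                assert counts[c.id] == 1

    def test_contig_order_invariance(self, default_run):
        truth, contigs, res = default_run
        from mitoscaffold import simulate_long_reads

        reads = simulate_long_reads(truth)
        shuffled = list(reversed(contigs))
        res2 = build_scaffolds(shuffled, reads)
        pairs = lambda r: set().union(*(s.junction_end_pairs() for s in r.scaffolds))
        assert pairs(res2) == pairs(res)
        assert len(res2.scaffolds) == len(res.scaffolds)

    def test_raising_min_support_never_adds_connections(self, default_run):
        truth, contigs, res = default_run
        from mitoscaffold import simulate_long_reads

        reads = simulate_long_reads(truth)
        strict = build_scaffolds(
            contigs, reads, ScaffoldParams(min_support=8)
        )
        pairs = lambda r: set().union(*(s.junction_end_pairs() for s in r.scaffolds))
        assert pairs(strict) <= pairs(res)
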