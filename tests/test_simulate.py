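"""The synthetic multipartite-mitogenome generator and its truth set."""

import edlib
import pytest

from mitoscaffold import (
    SimConfig,
    fragment_to_contigs,
    plant_mtpts,
    simulate_long_reads,
    simulate_mitogenome,
    simulate_plastome,
    simulate_short_reads,
)
from mitoscaffold.io import revcomp
from mitoscaffold.simulate import (
    ConfigError,
    LongReadSpec,
    MoleculeSpec,
    MtptSpec,
    ShortReadSpec,
)


def test_same_seed_gives_identical_truth_and_reads():
    a = simulate_mitogenome(SimConfig(seed=5))
    b = simulate_mitogenome(SimConfig(seed=5))
    assert a == b
    assert simulate_long_reads(a) == simulate_long_reads(b)
    assert simulate_short_reads(a) == simulate_short_reads(b)


def test_different_seed_gives_different_sequences():
    a = simulate_mitogenome(SimConfig(seed=1))
    b = simulate_mitogenome(SimConfig(seed=2))
    assert a.molecules[0].sequence != b.molecules[0].sequence


@pytest.mark.parametrize("seed", [0, 4, 9])
def test_conservation_of_genomic_material(seed):
    """Sum over contigs of length x relative coverage equals the total
    stoichiometry-weighted molecule length."""
    truth = simulate_mitogenome(
        SimConfig(seed=seed, molecules=(MoleculeSpec(True, 2), MoleculeSpec(False, 1)))
    )
    lhs = sum(
        len(truth.piece_sequence(pid)) * rel
        for pid, (_, rel) in truth.contig_truth.items()
    )
    rhs = sum(len(m) * m.copies for m in truth.molecules)
    assert lhs == rhs


def test_gc_close_to_target():
    truth = simulate_mitogenome(SimConfig(seed=3, gc_target=0.46))
    seq = "".join(m.sequence for m in truth.molecules)
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    assert abs(gc - 0.46) < 0.03


def test_no_repeats_means_unique_adjacencies_at_stoichiometry():
    truth = simulate_mitogenome(
        SimConfig(seed=2, n_repeat_families=0, n_alt_junctions=0,
                  n_embedded_repeat_pairs=0,
                  molecules=(MoleculeSpec(False, 3), MoleculeSpec(False, 1)))
    )
    pairs = [(a, b) for a, _, b, _, _ in truth.junction_table]
    assert len(pairs) == len(set(pairs))
    for pid, (kind, rel) in truth.contig_truth.items():
        assert kind == "unique"
        mol = next(m for m in truth.molecules
                   if any(p == pid for p, _ in truth.layouts[m.id][2]))
        assert rel == mol.copies


def test_repeat_relative_coverage_counts_genomic_copies():
    """Brute-force position count over the emitted molecules equals the
    declared expected relative coverage."""
    truth = simulate_mitogenome(SimConfig(seed=6))
    for fam, unit in truth.repeat_units.items():
        n_found = 0
        for m in truth.molecules:
            for probe in (unit, revcomp(unit)):
                start = 0
                while True:
                    i = m.sequence.find(probe, start)
                    if i < 0:
                        break
                    n_found += m.copies
                    start = i + 1
        assert n_found == truth.contig_truth[fam][1]


def test_alt_junction_family_has_four_distinct_flanks():
    truth = simulate_mitogenome(SimConfig(seed=8, n_alt_junctions=1))
    flanks = set()
    for a, _, b, _, _ in truth.junction_table:
        if a == "R1":
            flanks.add(b)
        if b == "R1":
            flanks.add(a)
    assert len(flanks) == 4


class TestFragmentToContigs:
    def test_unique_segments_give_equal_coverage_contigs(self):
        truth = simulate_mitogenome(
            SimConfig(seed=1, n_repeat_families=0, n_alt_junctions=0,
                      n_embedded_repeat_pairs=0, n_unique_segments=3,
                      molecules=(MoleculeSpec(False, 1),))
        )
        contigs, table = fragment_to_contigs(truth, base_depth=50.0)
        assert len(contigs) == 3
        assert set(table["mean_cov"]) == {50.0}

    def test_collapsed_repeat_has_double_coverage(self):
        truth = simulate_mitogenome(SimConfig(seed=1))
        contigs, _ = fragment_to_contigs(truth, base_depth=89.0)
        by_id = {c.id: c for c in contigs}
        assert by_id["R1"].mean_cov == pytest.approx(178.0)
        assert by_id["U1"].mean_cov == pytest.approx(89.0)

    def test_junction_trim_shortens_only_junction_facing_ends(self):
        truth = simulate_mitogenome(SimConfig(seed=1))
        full, _ = fragment_to_contigs(truth)
        trimmed, _ = fragment_to_contigs(truth, junction_trim=100)
        fl = {c.id: c.length for c in full}
        tl = {c.id: c.length for c in trimmed}
        assert all(tl[i] <= fl[i] for i in fl)
        assert any(tl[i] < fl[i] for i in fl)
        # trimmed contigs are substrings of the untrimmed pieces
        fs = {c.id: c.sequence for c in full}
        assert all(c.sequence in fs[c.id] for c in trimmed)


class TestLongReads:
    def test_error_free_reads_are_substrings_of_molecules(self):
        truth = simulate_mitogenome(SimConfig(seed=2))
        refs = [
            (m.sequence * 2) if m.circular else m.sequence for m in truth.molecules
        ]
        for read in simulate_long_reads(truth, LongReadSpec(depth=2)):
            assert any(
                read.sequence in ref or revcomp(read.sequence) in ref for ref in refs
            )

    def test_total_bases_match_requested_depth(self):
        truth = simulate_mitogenome(SimConfig(seed=2))
        genome = sum(len(m) * m.copies for m in truth.molecules)
        reads = simulate_long_reads(truth, LongReadSpec(depth=20))
        assert sum(len(r) for r in reads) == pytest.approx(20 * genome, rel=0.10)

    def test_mean_length_above_all_molecules_is_an_error(self):
        truth = simulate_mitogenome(SimConfig(seed=2))
        with pytest.raises(ConfigError):
            simulate_long_reads(truth, LongReadSpec(mean_len=10_000_000))


class TestShortReads:
    def test_insert_smaller_than_read_pair_is_an_error(self):
        truth = simulate_mitogenome(SimConfig(seed=2))
        with pytest.raises(ConfigError):
            simulate_short_reads(truth, ShortReadSpec(insert_mean=200.0))

    def test_pair_geometry_and_depth(self):
        truth = simulate_mitogenome(SimConfig(seed=2))
        r1, r2 = simulate_short_reads(truth, ShortReadSpec(depth=5))
        assert len(r1) == len(r2)
        assert all(len(r) == 150 for r in r1 + r2)
        genome = sum(len(m) * m.copies for m in truth.molecules)
        assert 300 * len(r1) == pytest.approx(5 * genome, rel=0.02)


class TestPlantMtpts:
    def test_zero_inserts_is_identity(self):
        truth = simulate_mitogenome(SimConfig(seed=1))
        assert plant_mtpts(truth, simulate_plastome(seed=1), MtptSpec(0)) is truth

    def test_inserts_recorded_in_both_coordinate_systems(self):
        plast = simulate_plastome(seed=4)
        truth = plant_mtpts(
            simulate_mitogenome(SimConfig(seed=4)),
            plast,
            MtptSpec(n_inserts=4, insert_len_range=(150, 300), identity=0.95),
        )
        assert len(truth.mtpt_truth) == 4
        mols = {m.id: m.sequence for m in truth.molecules}
        for t in truth.mtpt_truth:
            planted = mols[t.molecule_id][t.start : t.end]
            source = plast.sequence[t.plastome_start : t.plastome_end]
            if t.strand == "-":
                source = revcomp(source)
            ed = edlib.align(planted, source, mode="NW")["editDistance"]
            assert 1 - ed / len(source) == pytest.approx(0.95, abs=0.03)

    def test_identity_one_plants_verbatim_copy(self):
        plast = simulate_plastome(seed=4)
        truth = plant_mtpts(
            simulate_mitogenome(SimConfig(seed=4)),
            plast,
            MtptSpec(n_inserts=1, insert_len_range=(200, 200), identity=1.0),
        )
        t = truth.mtpt_truth[0]
        mols = {m.id: m.sequence for m in truth.molecules}
        planted = mols[t.molecule_id][t.start : t.end]
        source = plast.sequence[t.plastome_start : t.plastome_end]
        assert planted == (source if t.strand == "+" else revcomp(source))

    def test_bad_identity_is_an_error(self):
        truth = simulate_mitogenome(SimConfig(seed=1))
        with pytest.raises(ConfigError):
            plant_mtpts(truth, simulate_plastome(seed=1), MtptSpec(1, identity=1.5))


def test_infeasible_configs_are_rejected():
    with pytest.raises(ConfigError):
        SimConfig(seed=0, n_unique_segments=2).validate()  # < 2 per molecule
    with pytest.raises(ConfigError):
        # more repeat placements than junction slots
        simulate_mitogenome(SimConfig(seed=0, n_repeat_families=40))
    with pytest.raises(ConfigError):
        SimConfig(seed=0, molecules=(MoleculeSpec(False, 0),)).validate()
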