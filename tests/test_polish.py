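"""Short-read mapping, plastid-read removal and consensus polishing."""

import numpy as np
import pytest

from mitoscaffold import (
    MapParams,
    SeqRecord,
    SimConfig,
    assign_copy_class,
    build_scaffolds,
    extract_consensus,
    fragment_to_contigs,
    map_short_reads,
    polish_scaffolds,
    remove_plastid_reads,
    revcomp,
    select_mito_contigs,
    simulate_long_reads,
    simulate_mitogenome,
    simulate_plastome,
    simulate_short_reads,
)
from mitoscaffold.simulate import LongReadSpec, ShortReadSpec

from conftest import random_dna


def _tile_reads(ref: str, read_len=150, step=10, prefix="t"):
    return [
        SeqRecord(f"{prefix}{i}", ref[o : o + read_len])
        for i, o in enumerate(range(0, len(ref) - read_len + 1, step))
    ]


class TestMapping:
    ref = SeqRecord("ref", random_dna(3000, seed=40))

    def test_exact_read_contributes_depth_one_over_its_span(self):
        read = SeqRecord("r", self.ref.sequence[1000:1150])
        pile = map_short_reads([read], [self.ref])["ref"]
        depth = pile.depth
        assert depth[1000:1150].min() == 1
        assert depth[:1000].max() == 0 and depth[1150:].max() == 0

    def test_ten_percent_mismatch_read_unmapped_at_similarity_095(self):
        rng = np.random.default_rng(0)
        seq = list(self.ref.sequence[1000:1150])
        for i in rng.choice(150, size=15, replace=False):
            seq[i] = "ACGT"[("ACGT".index(seq[i]) + 1) % 4]
        pile = map_short_reads(
            [SeqRecord("r", "".join(seq))], [self.ref], MapParams(0.9, 0.95)
        )["ref"]
        assert pile.depth.sum() == 0

    def test_tiled_depth_matches_expectation(self):
        pile = map_short_reads(_tile_reads(self.ref.sequence), [self.ref])["ref"]
        # interior positions carry read_len/step = 15x
        assert pile.depth[200:2800].mean() == pytest.approx(15, rel=0.05)

    def test_raising_similarity_never_maps_more_reads(self):
        rng = np.random.default_rng(2)
        reads = []
        for j, o in enumerate(range(0, 2850, 30)):
            seq = list(self.ref.sequence[o : o + 150])
            for i in rng.choice(150, size=int(rng.integers(0, 14)), replace=False):
                seq[i] = "ACGT"[("ACGT".index(seq[i]) + 1) % 4]
            reads.append(SeqRecord(f"m{j}", "".join(seq)))

        def n_mapped(sim):
            pile = map_short_reads(reads, [self.ref], MapParams(0.9, sim))["ref"]
            return pile.counts[:4].sum()

        assert n_mapped(0.98) <= n_mapped(0.95) <= n_mapped(0.90)

    def test_empty_references_is_an_error(self):
        with pytest.raises(ValueError):
            map_short_reads([], [])

    def test_ambiguous_two_locus_read_is_dropped(self):
        unit = random_dna(400, seed=41)
        ref = SeqRecord(
            "r2", random_dna(800, seed=42) + unit + random_dna(800, seed=43) + unit
        )
        read = SeqRecord("q", unit[100:250])
        pile = map_short_reads([read], [ref])["r2"]
        assert pile.depth.sum() == 0


class TestPlastidRemoval:
    plastome = simulate_plastome(length=10000, seed=44)
    mito = SeqRecord("mt", random_dna(5000, seed=45))

    def test_plastome_read_removed_mito_read_retained(self):
        pr = SeqRecord("p", self.plastome.sequence[500:650])
        mr = SeqRecord("m", self.mito.sequence[500:650])
        kept = remove_plastid_reads([pr, mr], self.plastome)
        assert [r.id for r in kept] == ["m"]

    def test_mtpt_reads_partially_removed_but_regions_recoverable(self):
        """Reads from a planted plastome insert look plastid-like and may be
        excluded, yet MTPT detection still recovers the region from the
        assembled sequence itself."""
        from mitoscaffold import find_mtpts
        from mitoscaffold.simulate import MtptSpec, plant_mtpts

        truth = plant_mtpts(
            simulate_mitogenome(SimConfig(seed=5)),
            self.plastome,
            MtptSpec(n_inserts=2, insert_len_range=(300, 500), identity=0.98),
        )
        mols = truth.molecule_records()
        mtpt_reads = [
            SeqRecord(f"ins{i}", {m.id: m.sequence for m in mols}[t.molecule_id][t.start : t.start + 150])
            for i, t in enumerate(truth.mtpt_truth)
        ]
        kept = remove_plastid_reads(mtpt_reads, self.plastome)
        assert len(kept) < len(mtpt_reads)  # some MTPT reads are consumed
        regions, _ = find_mtpts(mols, self.plastome)
        assert len(regions) == 2


class TestConsensus:
    def test_planted_substitution_corrected_at_depth(self):
        ref = random_dna(2000, seed=46)
        broken = ref[:900] + ("A" if ref[900] != "A" else "C") + ref[901:]
        pile = map_short_reads(_tile_reads(ref), [SeqRecord("s", broken)])["s"]
        out, low = extract_consensus(pile, broken)
        assert out == ref
        # only the coverage ramp at the reference ends may be low
        assert all(e <= 60 or s >= 1940 for s, e in low)

    def test_zero_coverage_keeps_reference_and_reports_interval(self):
        ref = SeqRecord("s", random_dna(500, seed=47))
        pile = map_short_reads([SeqRecord("r", "ACGT" * 40)], [ref])["s"]
        out, low = extract_consensus(pile, ref.sequence)
        assert out == ref.sequence
        assert low == [(0, 500)]

    def test_below_threshold_variant_site_keeps_reference(self):
        ref = random_dna(400, seed=48)
        broken = ref[:200] + ("G" if ref[200] != "G" else "T") + ref[201:]
        reads = _tile_reads(ref, step=40)[:4]  # depth 4 < 5 at the variant
        pile = map_short_reads(reads, [SeqRecord("s", broken)])["s"]
        out, low = extract_consensus(pile, broken, low_cov_threshold=5)
        assert out == broken
        assert any(s <= 200 < e for s, e in low)

    def test_threshold_zero_unanimous_reads_reproduce_sampled_molecule(self):
        ref = random_dna(1500, seed=49)
        noisy = ref[:700] + ref[703:]  # 3 bp deletion in the reference copy
        pile = map_short_reads(_tile_reads(ref), [SeqRecord("s", noisy)])["s"]
        out, _ = extract_consensus(pile, noisy, low_cov_threshold=0)
        assert out == ref

    def test_low_cov_mode_n(self):
        ref = SeqRecord("s", random_dna(300, seed=50))
        pile = map_short_reads([], [ref])["s"]
        out, _ = extract_consensus(pile, ref.sequence, low_cov_mode="N")
        assert out == "N" * 300


class TestPolishScaffolds:
    @staticmethod
    def _small_run(seed):
        cfg = SimConfig(
            seed=seed,
            n_unique_segments=4,
            unique_len_range=(8000, 15000),
            n_repeat_families=1,
            n_embedded_repeat_pairs=2,
            long_reads=LongReadSpec(error_rate=0.05, depth=25),
            short_reads=ShortReadSpec(depth=30),
        )
        truth = simulate_mitogenome(cfg)
        contigs, _ = fragment_to_contigs(truth, junction_trim=100)
        select_mito_contigs(contigs)
        assign_copy_class(contigs)
        res = build_scaffolds(contigs, simulate_long_reads(truth))
        return truth, res

    def test_error_filled_junctions_polished_to_exact_truth(self):
        """Junctions filled from 5%-error long reads, polished with 30x
        error-free short reads, give the true molecules exactly, N-free."""
        truth, res = self._small_run(2)
        r1, r2 = simulate_short_reads(truth)
        polished, _log = polish_scaffolds(
            res.scaffolds, r1 + r2, simulate_plastome(seed=2)
        )
        refs = [
            (m.sequence * 2) if m.circular else m.sequence for m in truth.molecules
        ]
        for s in polished:
            assert "N" not in s.sequence
            assert any(
                s.sequence in ref or revcomp(s.sequence) in ref for ref in refs
            ), s.id

    def test_perfect_scaffolds_are_a_fixed_point_and_polish_converges(self):
        truth, res = self._small_run(5)
        r1, r2 = simulate_short_reads(truth)
        plast = simulate_plastome(seed=5)
        once, log1 = polish_scaffolds(res.scaffolds, r1 + r2, plast)
        twice, log2 = polish_scaffolds(once, r1 + r2, plast)
        assert [s.sequence for s in twice] == [s.sequence for s in once]
        assert log2["changes"].sum() == 0
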