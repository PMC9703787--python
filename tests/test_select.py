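"""Mitochondrial contig selection and coverage-based copy classes."""

import warnings

import pytest

from mitoscaffold import (
    ClassBands,
    Contig,
    SelectParams,
    SimConfig,
    assign_copy_class,
    compute_mean_coverage,
    fragment_to_contigs,
    select_mito_contigs,
    simulate_mitogenome,
    simulate_short_reads,
)
from mitoscaffold.select import SelectionError, classify_ratio
from mitoscaffold.simulate import MoleculeSpec, ShortReadSpec

from conftest import random_dna


def _contig(cid, length, cov, genes=()):
    return Contig(id=cid, sequence="A" * length, mean_cov=cov, gene_hits=list(genes))


class TestSelection:
    def test_gene_hit_selects_regardless_of_coverage(self):
        contigs = [
            _contig("a", 5000, 89, ["cox2"]),
            _contig("b", 5000, 32, ["nad5"]),
            _contig("hot", 1000, 150, ["cox1"]),  # outside [32, 89], short
        ]
        assert "hot" in select_mito_contigs(contigs)

    def test_coverage_criterion_with_inclusive_bounds(self):
        contigs = [
            _contig("g1", 5000, 32, ["cox1"]),
            _contig("g2", 5000, 139, ["nad1"]),
            _contig("in", 2500, 100),
            _contig("edge", 2000, 139.0),
            _contig("short", 1900, 100),
            _contig("deep", 5000, 300),
        ]
        sel = select_mito_contigs(contigs)
        assert sel == {"g1", "g2", "in", "edge"}

    def test_no_gene_hits_requires_explicit_range(self):
        contigs = [_contig("a", 5000, 100)]
        with pytest.raises(SelectionError, match="cov_range"):
            select_mito_contigs(contigs)
        sel = select_mito_contigs(contigs, SelectParams(cov_range=(32, 139)))
        assert sel == {"a"}

    def test_idempotent_and_order_invariant(self):
        def build():
            return [
                _contig("g", 5000, 80, ["cox1"]),
                _contig("b", 3000, 80),
                _contig("c", 3000, 200),
            ]

        a = build()
        first = select_mito_contigs(a)
        assert select_mito_contigs(a) == first
        b = list(reversed(build()))
        assert select_mito_contigs(b) == first

    def test_widening_range_never_deselects(self):
        contigs = [_contig("g", 5000, 80, ["cox1"])] + [
            _contig(f"c{i}", 3000, cov) for i, cov in enumerate([40, 80, 120, 200])
        ]
        narrow = select_mito_contigs(contigs, SelectParams(cov_range=(60, 100)))
        wide = select_mito_contigs(contigs, SelectParams(cov_range=(30, 210)))
        assert narrow <= wide


class TestCopyClass:
    def test_paper_style_partition(self):
        contigs = [
            _contig("med", 5000, 89, ["a"]),
            _contig("m2", 5000, 89, ["b"]),
            _contig("m3", 5000, 89, ["c"]),
            _contig("hi", 5000, 204, ["d"]),
            _contig("dbl", 5000, 178, ["e"]),
            _contig("low", 5000, 40, ["f"]),
        ]
        select_mito_contigs(contigs)
        med = assign_copy_class(contigs)
        assert med == 89
        by = {c.id: c for c in contigs}
        assert by["med"].copy_class == "single" and not by["med"].repeat_like
        assert by["hi"].cov_ratio == pytest.approx(2.29, abs=0.005)
        assert by["hi"].copy_class == "intermediate(2,3)" and by["hi"].repeat_like
        assert by["dbl"].copy_class == "multiple(2)"
        assert by["low"].copy_class == "low"

    @pytest.mark.parametrize(
        "ratio,expected,repeatish",
        [
            (0.5, "low", False),
            (1.0, "single", False),
            (1.24, "single", False),
            (1.25, "intermediate(1,2)", True),
            (1.9, "multiple(2)", True),
            (2.0, "multiple(2)", True),
            (2.29, "intermediate(2,3)", True),
            (2.9, "multiple(3)", True),
        ],
    )
    def test_band_boundaries(self, ratio, expected, repeatish):
        assert classify_ratio(ratio, ClassBands()) == (expected, repeatish)

    def test_zero_median_is_an_error(self):
        contigs = [_contig(f"c{i}", 5000, 0.0, ["g"]) for i in range(3)]
        select_mito_contigs(contigs)
        with pytest.raises(SelectionError):
            assign_copy_class(contigs)

    def test_needs_three_selected(self):
        contigs = [_contig("a", 5000, 10, ["g"])]
        select_mito_contigs(contigs)
        with pytest.raises(SelectionError):
            assign_copy_class(contigs)

    def test_recovery_on_noise_free_truth(self):
        """Every multi-copy repeat contig is classed repeat-like and every
        single-copy unique contig single, from coverage alone."""
        truth = simulate_mitogenome(SimConfig(seed=9))
        contigs, _ = fragment_to_contigs(truth, noise_sd=0.0)
        select_mito_contigs(contigs)
        assign_copy_class(contigs)
        for c in contigs:
            kind, rel = truth.contig_truth[c.id]
            if kind == "repeat" and rel >= 2:
                assert c.repeat_like, c.id
            if kind == "unique" and rel == 1:
                assert c.copy_class == "single", c.id


class TestMeanCoverage:
    def test_zero_reads_warns_and_zeroes(self):
        contigs = [_contig("a", 3000, 50)]
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            table = compute_mean_coverage(contigs, [])
        assert contigs[0].mean_cov == 0.0
        assert table["mean_cov"].tolist() == [0.0]
        assert any("coverage" in str(x.message) for x in w)

    def test_simulated_depth_recovered_and_repeat_doubled(self):
        """Mapping-based mean coverage matches the simulated depth on unique
        contigs and doubles on the collapsed two-copy repeat contig."""
        truth = simulate_mitogenome(
            SimConfig(
                seed=3,
                n_unique_segments=4,
                unique_len_range=(6000, 9000),
                n_repeat_families=1,
                n_embedded_repeat_pairs=0,
                molecules=(MoleculeSpec(False, 1), MoleculeSpec(False, 1)),
            )
        )
        contigs, _ = fragment_to_contigs(truth)
        r1, r2 = simulate_short_reads(truth, ShortReadSpec(depth=30))
        compute_mean_coverage(contigs, r1 + r2)
        by = {c.id: c for c in contigs}
        uniques = [by[f"U{i}"].mean_cov for i in range(1, 5)]
        for cov in uniques:
            assert cov == pytest.approx(30, rel=0.15)
        mean_unique = sum(uniques) / 4
        assert by["R1"].mean_cov == pytest.approx(2 * mean_unique, rel=0.15)
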