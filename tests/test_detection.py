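"""Editing-level arithmetic, substitution typing and the site caller."""

import numpy as np
import pytest

from mitoedit import (
    CircularGenome,
    SimConfig,
    Thresholds,
    call_sites,
    classify_substitution,
    editing_level,
    generate_genome,
    heterogeneity,
    plant_edits,
    simulate_pileups,
    sites_above,
)
from mitoedit.detection import read_sites_vcf, write_sites_vcf
from mitoedit.genome import GeneModel
from mitoedit.pileup import BASE_INDEX, PileupTable, SiteCounts


def counts(pos=1, A=0, C=0, G=0, T=0):
    return SiteCounts(pos, A, C, G, T)


class TestHeterogeneity:
    def test_pure_reference_scores_zero(self):
        assert heterogeneity(counts(A=1000), "A") == 0.0

    def test_major_nonref_fraction(self):
        assert heterogeneity(counts(A=734, G=266), "A") == pytest.approx(26.6)

    def test_majority_nonref_allele_only(self):
        assert heterogeneity(counts(A=930, G=40, T=30), "A") == pytest.approx(4.0)

    def test_zero_depth_is_missing(self):
        assert heterogeneity(counts(), "A") is None

    def test_alternative_mode(self):
        assert heterogeneity(counts(A=930, G=40, T=30), "A",
                             mode="one_minus_major") == pytest.approx(7.0)


class TestEditingLevel:
    @pytest.mark.parametrize("ref,kw,alt,expected", [
        ("A", dict(A=50, G=50), "G", 50.0),
        ("A", dict(G=120), "G", 100.0),
        ("C", dict(C=10, T=90), "T", 90.0),
    ])
    def test_formula(self, ref, kw, alt, expected):
        assert editing_level(ref, counts(**kw), alt) == pytest.approx(expected)

    def test_zero_depth_missing(self):
        assert editing_level("A", counts(), "G") is None

    def test_same_allele_rejected(self):
        with pytest.raises(ValueError):
            editing_level("A", counts(A=5), "A")


class TestClassify:
    @pytest.mark.parametrize("ref,alt,strand,expected", [
        ("A", "G", "+", "A-to-I"),
        ("T", "C", "-", "A-to-I"),  # A>G on the minus-strand transcript
        ("C", "T", "+", "C-to-U"),
        ("G", "A", "-", "C-to-U"),
        ("G", "A", "+", "other"),
        ("A", "C", "+", "other"),
    ])
    def test_typing(self, ref, alt, strand, expected):
        _, ttype = classify_substitution(ref, alt, strand)
        assert ttype == expected

    def test_unassigned_strand_keeps_raw_type(self):
        raw, ttype = classify_substitution("A", "G", "unassigned")
        assert ttype == "unassigned"
        assert raw.startswith("A>G")

    def test_invalid_nucleotide(self):
        with pytest.raises(ValueError):
            classify_substitution("A", "X", "+")


def _tables(genome, dna_spec, rna_spec):
    """Build DNA/RNA pileups with uniform reference background plus
    per-position overrides {pos: {base: count}}."""
    tables = []
    for spec, depth in ((dna_spec, 100), (rna_spec, 100)):
        t = PileupTable.zeros("s", genome.length)
        for i, b in enumerate(genome.sequence):
            t.counts[i, BASE_INDEX[b]] = depth
        for pos, override in spec.items():
            t.counts[pos - 1] = 0
            for b, n in override.items():
                t.counts[pos - 1, BASE_INDEX[b]] = n
        tables.append(t)
    return tables


@pytest.fixture
def small_genome():
    return CircularGenome(id="g", sequence="A" * 30)


@pytest.fixture
def plus_gene():
    return [GeneModel("x", "CDS", 1, 30, "+")]


class TestCallSites:
    def test_simple_a_to_i_call(self, small_genome, plus_gene):
        dna, rna = _tables(small_genome, {}, {5: {"G": 95, "A": 5}})
        sites = call_sites(dna, rna, small_genome, plus_gene)
        assert len(sites) == 1
        s = sites[0]
        assert (s.position, s.ref_base, s.alt_base) == (5, "A", "G")
        assert s.transcript_type == "A-to-I"
        assert s.editing_level == pytest.approx(95.0)
        assert s.gene_ids == ("x",)

    def test_coverage_filter_strictly_more_than_ten(self, small_genome, plus_gene):
        dna, rna = _tables(small_genome, {}, {5: {"G": 8}, 9: {"G": 10},
                                              12: {"G": 11}})
        sites = call_sites(dna, rna, small_genome, plus_gene)
        assert [s.position for s in sites] == [12]

    def test_heterogeneous_dna_site_flagged(self, small_genome, plus_gene):
        dna, rna = _tables(small_genome, {7: {"A": 70, "G": 30}},
                           {7: {"G": 90, "A": 10}})
        sites = call_sites(dna, rna, small_genome, plus_gene)
        (s,) = sites
        assert s.excluded_heterogeneous
        assert s.dna_heterogeneity == pytest.approx(30.0)
        assert sites_above(sites, 50.0) == []  # excluded from summaries

    def test_opposite_strand_overlap_is_unassigned(self, small_genome):
        genes = [GeneModel("p", "ORF", 1, 15, "+"),
                 GeneModel("m", "ORF", 10, 21, "-")]
        dna, rna = _tables(small_genome, {}, {12: {"G": 90, "A": 10}})
        (s,) = call_sites(dna, rna, small_genome, genes)
        assert s.transcript_type == "unassigned"
        assert set(s.gene_ids) == {"p", "m"}

    def test_zero_dna_depth_site_not_called(self, small_genome, plus_gene):
        dna, rna = _tables(small_genome, {5: {}}, {5: {"G": 50}})
        assert call_sites(dna, rna, small_genome, plus_gene) == []

    def test_length_mismatch_rejected(self, small_genome, plus_gene):
        dna = PileupTable.zeros("d", 10)
        rna = PileupTable.zeros("r", 30)
        with pytest.raises(ValueError):
            call_sites(dna, rna, small_genome, plus_gene)


class TestOnSyntheticData:
    def test_zero_false_positives_without_error(self):
        config = SimConfig(seed=31, n_edit_sites=0, frac_noncoding=0.0,
                           restorative_mode=False, error_rate=0.0)
        genome, models = generate_genome(config)
        truth = plant_edits(genome, models, config)
        assert len(truth) == 0
        dna, rna = simulate_pileups(genome, truth, config)
        assert call_sites(dna, rna, genome, models) == []

    def test_recovery_of_planted_sites(self, default_sim, default_sites):
        config, genome, models, truth, _, _ = default_sim
        by_pos = {s.position: s for s in default_sites}
        truth_called = truth[truth["level"] > 50.0]
        n_within = 0
        for _, row in truth_called.iterrows():
            s = by_pos.get(int(row["pos"]))
            assert s is not None, f"site {row['pos']} not recovered"
            if abs(s.editing_level - row["level"]) <= 3.0:
                n_within += 1
        assert n_within / len(truth_called) >= 0.99

    def test_typing_closure_default_simulator(self, default_sim, default_sites):
        """With only A->G / C->T planted, no called single-strand-gene site
        types as 'other'."""
        in_gene = [s for s in sites_above(default_sites, 50.0)
                   if s.strand in "+-"]
        assert in_gene
        assert {s.transcript_type for s in in_gene} <= {"A-to-I", "C-to-U"}

    @pytest.mark.parametrize("stricter", [
        Thresholds(min_rna_depth=200),
        Thresholds(call_level_pct=80.0),
        Thresholds(min_rna_depth=50, call_level_pct=95.0),
    ])
    def test_monotonicity_in_thresholds(self, default_sim, default_sites, stricter):
        config, genome, models, _, dna, rna = default_sim
        base = sites_above(call_sites(dna, rna, genome, models, Thresholds()),
                           Thresholds().call_level_pct)
        strict = sites_above(call_sites(dna, rna, genome, models, stricter),
                             stricter.call_level_pct)
        assert len(strict) <= len(base)


def test_vcf_round_trip(tmp_path, default_sim, default_sites):
    _, genome, *_ = default_sim
    path = tmp_path / "edits.vcf"
    write_sites_vcf(default_sites, genome, path)
    back = read_sites_vcf(path)
    assert len(back) == len(default_sites)
    for a, b in zip(default_sites, back):
        assert (a.position, a.ref_base, a.alt_base) == (b.position, b.ref_base, b.alt_base)
        assert a.editing_level == pytest.approx(b.editing_level, abs=1e-3)
        assert a.transcript_type == b.transcript_type
        assert a.excluded_heterogeneous == b.excluded_heterogeneous
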