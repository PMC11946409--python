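"""Nei–Gojobori site/difference counting against a brute-force oracle."""

from itertools import permutations, product

import numpy as np
import pytest

from mitoedit import (
    Thresholds,
    apply_edits,
    kaks_table,
    ng_diff_counts,
    ng_kaks,
    ng_site_counts,
    sites_above,
)
from mitoedit.genome import codon_table, translate_codon
from mitoedit.kaks import CdsEdit, jukes_cantor


# -- independent oracle ------------------------------------------------------
# A direct enumeration written against the NG86 definitions, used only to
# cross-check the implementation.

def oracle_translate(codon, table_id=1):
    t = codon_table(table_id)
    return "*" if codon in t.stop_codons else t.forward_table[codon]


def oracle_site_counts(codon, table_id=1):
    aa = oracle_translate(codon, table_id)
    syn = 0.0
    for i, b in product(range(3), "ACGT"):
        if b == codon[i]:
            continue
        mut = codon[:i] + b + codon[i + 1:]
        mut_aa = oracle_translate(mut, table_id)
        if mut_aa == aa and mut_aa != "*":
            syn += 1 / 3
    return syn, 3 - syn


def oracle_diff_counts(ca, cb, table_id=1):
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    if not diffs:
        return 0.0, 0.0
    pathways = []
    for order in permutations(diffs):
        cur, syn, nonsyn, through_stop = ca, 0, 0, False
        for i in order:
            nxt = cur[:i] + cb[i] + cur[i + 1:]
            a1, a2 = oracle_translate(cur, table_id), oracle_translate(nxt, table_id)
            if a1 == a2 and "*" not in (a1, a2):
                syn += 1
            else:
                nonsyn += 1
            if a2 == "*":
                through_stop = True
            cur = nxt
        pathways.append((syn, nonsyn, through_stop))
    ok = [(s, n) for s, n, stop in pathways if not stop]
    if not ok:
        ok = [(s, n) for s, n, _ in pathways]
    return (sum(s for s, _ in ok) / len(ok), sum(n for _, n in ok) / len(ok))


def sense_codons(table_id=1):
    t = codon_table(table_id)
    return sorted(set("".join(c) for c in product("ACGT", repeat=3))
                  - set(t.stop_codons))


# -- unit examples -----------------------------------------------------------

class TestSiteCounts:
    @pytest.mark.parametrize("codon,syn", [
        ("TTT", 1 / 3),  # only TTT->TTC is synonymous
        ("ATG", 0.0),    # Met has no synonymous neighbour
        ("GGG", 1.0),    # fully degenerate third position
    ])
    def test_known_codons(self, codon, syn):
        s, n = ng_site_counts(codon)
        assert s == pytest.approx(syn)
        assert s + n == pytest.approx(3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng_site_counts("TAA")

    def test_all_sense_codons_match_oracle(self):
        for codon in sense_codons():
            assert ng_site_counts(codon) == pytest.approx(
                oracle_site_counts(codon))


class TestDiffCounts:
    @pytest.mark.parametrize("a,b,expected", [
        ("TTT", "TTT", (0.0, 0.0)),
        ("TTT", "TTC", (1.0, 0.0)),  # Phe->Phe
        ("ACG", "GCG", (0.0, 1.0)),  # Thr->Ala
    ])
    def test_simple_pairs(self, a, b, expected):
        assert ng_diff_counts(a, b) == pytest.approx(expected)

    def test_two_diff_pathway_average(self):
        # TTG vs AGG: both 2-step pathways counted by the oracle
        assert ng_diff_counts("TTG", "AGG") == pytest.approx(
            oracle_diff_counts("TTG", "AGG"))

    def test_length_checked(self):
        with pytest.raises(ValueError):
            ng_diff_counts("TT", "TTC")

    def test_random_codon_pairs_match_oracle(self):
        rng = np.random.default_rng(1234)
        codons = sense_codons()
        for _ in range(500):
            a, b = (codons[i] for i in rng.integers(0, len(codons), 2))
            assert ng_diff_counts(a, b) == pytest.approx(oracle_diff_counts(a, b))
            # conservation: diffs sum to number of differing positions
            sd, nd = ng_diff_counts(a, b)
            assert sd + nd == pytest.approx(sum(x != y for x, y in zip(a, b)))


class TestApplyEdits:
    def test_above_threshold_applied(self):
        edits = [CdsEdit(5, "A", "G", 99.0)]
        assert apply_edits("ATGTAGAAATAA", edits, 50.0) == "ATGTGGAAATAA"

    def test_threshold_is_strict(self):
        edits = [CdsEdit(5, "A", "G", 40.0)]
        assert apply_edits("ATGTAGAAATAA", edits, 50.0) == "ATGTAGAAATAA"
        assert apply_edits("ATGTAGAAATAA", edits, 39.0) == "ATGTGGAAATAA"

    def test_two_edits_in_one_codon(self):
        edits = [CdsEdit(4, "T", "C", 80.0), CdsEdit(6, "A", "G", 80.0)]
        assert apply_edits("ATGTAAAAATAA", edits, 50.0) == "ATGCAGAAATAA"

    def test_ref_mismatch_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            apply_edits("ATG", [CdsEdit(2, "A", "G", 99.0)], 50.0)


class TestNgKaks:
    def test_identical_sequences(self):
        r = ng_kaks("ATGTTTGGG", "ATGTTTGGG")
        assert r.n_subs == 0
        assert r.Ka is None and r.Ks is None and r.ka_ks is None

    def test_identical_sequences_strict_zero_mode(self):
        r = ng_kaks("ATGTTTGGG", "ATGTTTGGG", zero_subs_na=False)
        assert r.Ka == 0.0 and r.Ks == 0.0 and r.ka_ks is None

    def test_all_nonsynonymous_gives_ks_na(self):
        # ACG->GCG (Thr->Ala) and AAA->GAA (Lys->Glu): only nonsynonymous
        r = ng_kaks("ACGAAA", "GCGGAA")
        assert r.syn_subs == 0 and r.nonsyn_subs == 2
        assert r.Ka is not None and r.Ka > 0
        assert r.Ks is None and r.ka_ks is None

    def test_synonymous_only_pair(self):
        # one third-position Gly->Gly change over four glycine codons keeps
        # ps below the Jukes-Cantor saturation bound
        r = ng_kaks("GGGGGTGGAGGC", "GGAGGTGGAGGC")
        assert r.nonsyn_subs == 0 and r.syn_subs == 1
        assert r.Ka == 0.0
        assert r.Ks is not None and r.Ks > 0
        assert r.ka_ks == 0.0  # Ka = 0 with a defined positive Ks

    def test_stop_containing_codon_pairs_dropped(self):
        # second codon is a stop in sequence a: pair eliminated pairwise
        r = ng_kaks("ATGTAGTTT", "ATGTGGTTT")
        assert r.n_codons_analyzed == 2
        assert r.n_subs == 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ng_kaks("ATG", "ATGAAA")

    def test_symmetry_and_conservation_on_random_pairs(self):
        rng = np.random.default_rng(99)
        codons = sense_codons()
        for _ in range(100):
            n = int(rng.integers(2, 20))
            a = "".join(codons[i] for i in rng.integers(0, len(codons), n))
            b = "".join(codons[i] for i in rng.integers(0, len(codons), n))
            r = ng_kaks(a, b)
            s = ng_kaks(b, a)
            for attr in ("S", "N", "Sd", "Nd", "Ka", "Ks"):
                x, y = getattr(r, attr), getattr(s, attr)
                if x is None:
                    assert y is None
                else:
                    assert x == pytest.approx(y)
            assert r.S + r.N == pytest.approx(3 * r.n_codons_analyzed)
            if r.Ka is not None:
                assert r.Ka >= 0
                assert (r.Ka == 0) == (r.Nd == 0)
            # oracle equivalence on S, N, Sd, Nd
            S_o = sum((oracle_site_counts(a[i:i+3])[0] +
                       oracle_site_counts(b[i:i+3])[0]) / 2
                      for i in range(0, 3 * n, 3))
            Sd_o = sum(oracle_diff_counts(a[i:i+3], b[i:i+3])[0]
                       for i in range(0, 3 * n, 3))
            Nd_o = sum(oracle_diff_counts(a[i:i+3], b[i:i+3])[1]
                       for i in range(0, 3 * n, 3))
            assert r.S == pytest.approx(S_o)
            assert r.Sd == pytest.approx(Sd_o)
            assert r.Nd == pytest.approx(Nd_o)

    def test_jukes_cantor_saturation_is_na(self):
        assert jukes_cantor(0.8) is None
        assert jukes_cantor(0.0) == 0.0


class TestEndToEnd:
    def test_table_signature_on_restorative_synthetic_data(self, default_sim,
                                                           default_sites):
        """All-nonsynonymous editing yields Syn-Subs = 0 and Ks = NA in
        every gene row."""
        config, genome, models, _, _, _ = default_sim
        table = kaks_table(genome, models, default_sites)
        assert len(table) == config.n_cds
        assert (table["syn_subs"] == 0).all()
        assert (table["Ks"] == "NA").all()
        assert (table["Ka/Ks"] == "NA").all()
        with_subs = table[table["subs"] > 0]
        assert (with_subs["nonsyn_subs"] == with_subs["subs"]).all()
        assert all(ka != "NA" and ka > 0 for ka in with_subs["Ka"])
        zero = table[table["subs"] == 0]
        assert (zero["Ka"] == "NA").all()

    def test_subs_match_applied_sites(self, default_sim, default_sites):
        config, genome, models, truth, _, _ = default_sim
        table = kaks_table(genome, models, default_sites).set_index("gene")
        applied = sites_above(default_sites, 50.0)
        for m in models:
            if not m.is_coding:
                continue
            # designed nonsynonymous (non-stop) sites above 50% in this gene
            n_designed = sum(
                1 for s in applied
                if m.contains(s.position, genome.length)
                and truth.set_index("pos").loc[s.position, "effect"]
                == "nonsynonymous")
            assert table.loc[m.gene_id, "subs"] == n_designed
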