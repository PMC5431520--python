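"""Divergence statistics: p-distance, Nei-Gojobori, RSCU, composition."""

import math

import numpy as np
import pytest

from mito_orfan.divergence import (CodonAlignment, composition,
                                   fm_divergence_report, nei_gojobori,
                                   p_distance, rscu)
from mito_orfan.simulate import PCG_LENGTHS, SimConfig, make_ancestor, _evolve_builder

from oracles import ng_pathway_counts, ng_site_fractions


class TestPDistance:
    @pytest.mark.parametrize("a,b,expected", [
        ("ACGT", "ACGT", 0.0),
        ("ACGT", "ACGA", 0.25),
        ("ACGN", "ACTA", 1 / 3),  # N column excluded from both counts
        ("AC-T", "ACGT", 0.0),    # gap column excluded
    ])
    def test_examples(self, a, b, expected):
        assert p_distance(a, b, "nt") == pytest.approx(expected)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            p_distance("ACG", "AC")

    def test_symmetric_bounded_and_zero_iff_identical(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(30):
            n = int(rng.integers(10, 60))
            a = "".join(bases[rng.integers(0, 4, n)])
            b = "".join(bases[rng.integers(0, 4, n)])
            d = p_distance(a, b)
            assert d == p_distance(b, a)
            assert 0.0 <= d <= 1.0
            assert (d == 0.0) == (a == b)


class TestNeiGojobori:
    def test_identical_sequences(self):
        aln = CodonAlignment("x", "ATGAAA", "ATGAAA")
        r = nei_gojobori(aln)
        assert r.dN == 0 and r.dS == 0 and r.omega is None
        assert "omega_undefined_dS_zero" in r.flags

    def test_synonymous_pair_ttt_ttc(self):
        """TTT vs TTC (both Phe): one synonymous difference on 1/3 of a
        synonymous site; uncorrected pS = 3.0, omega = 0."""
        r = nei_gojobori(CodonAlignment("x", "TTT", "TTC"), correction="none")
        assert r.Nd == 0 and r.Sd == 1
        assert r.S_sites == pytest.approx(1 / 3)
        assert r.pS == pytest.approx(3.0)
        assert "pS_exceeds_1" in r.flags
        assert r.pN == 0 and r.omega == 0

    def test_nonsynonymous_pair_gaa_gat(self):
        r = nei_gojobori(CodonAlignment("x", "GAA", "GAT"))
        assert r.Sd == 0 and r.Nd == 1
        assert r.omega is None and "omega_undefined_dS_zero" in r.flags

    def test_site_counts_partition_three_per_codon(self, rng):
        from oracles import STOP5
        codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                  if a + b + c not in STOP5]
        for _ in range(20):
            pair = rng.choice(len(codons), size=8)
            a = "".join(codons[i] for i in pair)
            pair2 = rng.choice(len(codons), size=8)
            b = "".join(codons[i] for i in pair2)
            r = nei_gojobori(CodonAlignment("x", a, b))
            assert r.S_sites + r.N_sites == pytest.approx(3 * 8, abs=1e-9)
            expected_diffs = sum(sum(ng_pathway_counts(a[i:i + 3], b[i:i + 3]))
                                 for i in range(0, 24, 3))
            assert r.Sd + r.Nd == pytest.approx(expected_diffs, abs=1e-9)
            expected_s = sum(ng_site_fractions(a[i:i + 3]) +
                             ng_site_fractions(b[i:i + 3])
                             for i in range(0, 24, 3)) / 2
            assert r.S_sites == pytest.approx(expected_s, abs=1e-9)

    def test_gap_codons_excluded_pairwise(self):
        aln = CodonAlignment("x", "ATG---AAA", "ATGCCCAAA")
        r = nei_gojobori(aln)
        assert r.n_codons == 2

    @pytest.mark.parametrize("omega_true", [0.1, 0.33, 1.0])
    def test_omega_recovery_under_codon_model(self, omega_true):
        """NG estimate recovers the generator's omega within 0.1 at 1e4 codons."""
        from mito_orfan.simulate import Segment, GenomeBuilder, _make_cds
        rng = np.random.default_rng(int(omega_true * 100))
        cds = _make_cds(rng, 30000, 0.6)
        b = GenomeBuilder([Segment(seq=cds, name="cox1", kind="PCG",
                                   coding=True, emit=True)])
        ref = b.copy()
        _evolve_builder(rng, b, 0.25, omega_true, 1.0, ref=ref)
        r = nei_gojobori(CodonAlignment("cox1", ref.segments[0].seq,
                                        b.segments[0].seq))
        assert r.omega == pytest.approx(omega_true, abs=0.1)


class TestRscuComposition:
    def test_two_codon_family_used_equally(self):
        table = rscu(["GAAGAG"])  # Glu: GAA/GAG
        glu = table[table.aa == "E"].set_index("codon")
        assert glu.loc["GAA", "rscu"] == 1.0 and glu.loc["GAG", "rscu"] == 1.0

    def test_four_codon_family_single_codon(self):
        table = rscu(["GGAGGAGGAGGA"])  # Gly family GGN
        gly = table[table.aa == "G"].set_index("codon")
        assert gly.loc["GGA", "rscu"] == 4.0
        assert (gly.drop("GGA").rscu == 0).all()

    def test_unused_family_flagged_zero(self):
        table = rscu(["ATGATG"])
        trp = table[table.aa == "W"]
        assert trp.unused_family.all() and (trp.rscu == 0).all()

    def test_rscu_matches_direct_count_oracle(self, rng):
        from oracles import STOP5, aa_of
        codons = [c for c in (a + b + d for a in "ACGT" for b in "ACGT"
                              for d in "ACGT") if c not in STOP5]
        cds = "".join(codons[i] for i in rng.integers(0, len(codons), 300))
        table = rscu([cds]).set_index("codon")
        counts = {c: 0 for c in codons}
        for i in range(0, len(cds), 3):
            counts[cds[i:i + 3]] += 1
        for codon in codons:
            fam = [c for c in codons if aa_of(c) == aa_of(codon)]
            tot = sum(counts[c] for c in fam)
            expected = counts[codon] * len(fam) / tot if tot else 0.0
            assert table.loc[codon, "rscu"] == pytest.approx(expected)

    @pytest.mark.parametrize("seq,key,expected", [
        ("AATT", "AT%", 100.0),
        ("AATT", "AT_skew", 0.0),
        ("GGGC", "GC_skew", 0.5),
    ])
    def test_composition_examples(self, seq, key, expected):
        assert composition(seq)[key] == pytest.approx(expected)

    def test_composition_fractions_sum_to_one_n_excluded(self, rng):
        bases = np.array(list("ACGTN"))
        seq = "".join(bases[rng.integers(0, 5, 200)])
        c = composition(seq)
        assert c["fA"] + c["fC"] + c["fG"] + c["fT"] == pytest.approx(1.0)
        assert c["fA"] == pytest.approx(
            seq.count("A") / sum(seq.count(b) for b in "ACGT"))


class TestFmReport:
    def test_self_comparison_is_zero(self, fm_pair):
        F, _ = fm_pair
        rep = fm_divergence_report(F, F)
        concat = rep[rep.gene == "concatenated"].iloc[0]
        assert concat.p_nt == 0 and concat.p_aa == 0
        assert math.isnan(concat.omega)

    def test_synthetic_pair_hits_divergence_target(self, fm_pair):
        F, M = fm_pair
        rep = fm_divergence_report(F, M)
        concat = rep[rep.gene == "concatenated"].iloc[0]
        assert concat.p_nt == pytest.approx(0.40, abs=0.02)
        assert concat.omega == pytest.approx(0.33, abs=0.1)
        assert set(rep.gene) >= set(PCG_LENGTHS) | {"concatenated", "gene_mean",
                                                    "rrnS", "rrnL"}
        rrn = rep[rep.gene == "rrnS"].iloc[0]
        assert 0 < rrn.p_nt < 0.75 and math.isnan(rrn.get("omega", float("nan")))

    def test_extended_cox2_aligns_as_overhang(self, fm_pair):
        F, M = fm_pair
        rep = fm_divergence_report(F, M)
        cox2 = rep[rep.gene == "cox2"].iloc[0]
        # only the shared core is compared, so p stays near the target
        assert cox2.p_nt == pytest.approx(0.40, abs=0.06)
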