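"""Genome model: GenBank round trips, coordinates, UR extraction."""

import numpy as np
import pytest

from mito_orfan.genome import (AnnotatedGenome, GeneFeature,
                               extract_unassigned_regions, normalize_gene_name,
                               read_genbank, write_genbank)
from mito_orfan.simulate import SimConfig, make_ancestor


def _complement_intervals(length, intervals):
    """Brute-force complement of covered bases (oracle)."""
    covered = np.zeros(length, dtype=bool)
    for s, e in intervals:
        if e <= length:
            covered[s:e] = True
        else:
            covered[s:] = True
            covered[: e - length] = True
    free = []
    i = 0
    while i < length:
        if not covered[i]:
            j = i
            while j < length and not covered[j]:
                j += 1
            free.append((i, j))
            i = j
        else:
            i += 1
    return free


@pytest.fixture(scope="module")
def ancestor_genome():
    b = make_ancestor(SimConfig(seed=5))
    g, _ = b.assemble("SYN1", "Synthetica exempli", "F")
    return g


class TestGenBankIO:
    def test_round_trip_identity(self, ancestor_genome, tmp_path):
        path = tmp_path / "g.gb"
        write_genbank(ancestor_genome, path)
        back = read_genbank(path)
        assert back.sequence == ancestor_genome.sequence
        assert back.route == ancestor_genome.route
        assert [(f.name, f.start, f.end, f.strand, f.kind) for f in back.features] == \
            [(f.name, f.start, f.end, f.strand, f.kind) for f in ancestor_genome.features]

    def test_one_based_inclusive_locations_on_write(self, tmp_path):
        g = AnnotatedGenome(
            id="MINI", organism="Mini", route="unknown", sequence="ACGT" * 25,
            features=[GeneFeature(name="cox1", kind="PCG", start=0, end=30)])
        write_genbank(g, tmp_path / "m.gb")
        assert "1..30" in (tmp_path / "m.gb").read_text()

    def test_wrapping_feature_round_trip(self, tmp_path):
        g = AnnotatedGenome(
            id="WRAP", organism="Wrap", route="unknown", sequence="ACGT" * 30,
            features=[GeneFeature(name="cox1", kind="PCG", start=100, end=130)])
        write_genbank(g, tmp_path / "w.gb")
        text = (tmp_path / "w.gb").read_text()
        assert "join" in text
        back = read_genbank(tmp_path / "w.gb")
        f = back.features[0]
        assert (f.start, f.end) == (100, 130)

    def test_empty_feature_list_writes_sequence_only(self, tmp_path, caplog):
        g = AnnotatedGenome(id="BARE", organism="Bare", route="unknown",
                            sequence="ACGT" * 10)
        with caplog.at_level("WARNING", logger="mito_orfan"):
            write_genbank(g, tmp_path / "b.gb")
        assert "sequence-only" in caplog.text
        assert read_genbank(tmp_path / "b.gb").sequence == g.sequence


class TestVocabulary:
    @pytest.mark.parametrize("raw,expected", [
        ("COI", ("cox1", "PCG")),
        ("ND4L", ("nad4L", "PCG")),
        ("16S ribosomal RNA", ("rrnL", "rRNA")),
        ("tRNA-Leu(UUR)", ("trnL2", "tRNA")),
        ("F-orf", ("F-orf", "ORFan")),
        ("pseudo:atp8", ("pseudo:atp8", "pseudogene_fragment")),
        ("mystery-gene", ("mystery-gene", "other")),
    ])
    def test_synonym_normalization(self, raw, expected):
        assert normalize_gene_name(raw) == expected


class TestUnassignedRegions:
    def test_fully_tiled_genome_has_no_urs(self):
        g = AnnotatedGenome(
            id="T", organism="t", route="unknown", sequence="A" * 90,
            features=[GeneFeature(name="cox1", kind="PCG", start=0, end=45),
                      GeneFeature(name="cox2", kind="PCG", start=45, end=90)])
        assert extract_unassigned_regions(g) == []

    def test_gap_upstream_of_cox1_gets_index_one(self):
        seq = "A" * 1000
        feats = [GeneFeature(name="nad1", kind="PCG", start=0, end=100),
                 GeneFeature(name="g150_200", kind="other", start=150, end=200),
                 GeneFeature(name="cox1", kind="PCG", start=200, end=500),
                 GeneFeature(name="g500_900", kind="other", start=500, end=900),
                 GeneFeature(name="g950_1000", kind="other", start=950, end=1000)]
        g = AnnotatedGenome(id="X", organism="x", route="unknown",
                            sequence=seq, features=feats)
        urs = extract_unassigned_regions(g)
        by_index = {u.index: (u.start, u.end) for u in urs}
        assert by_index[1] == (100, 150)  # the UR abutting cox1's start
        assert by_index[2] == (900, 950)

    def test_missing_anchor_raises(self):
        g = AnnotatedGenome(
            id="N", organism="n", route="unknown", sequence="A" * 100,
            features=[GeneFeature(name="nad1", kind="PCG", start=10, end=40)])
        with pytest.raises(ValueError, match="cox1"):
            extract_unassigned_regions(g)
        assert extract_unassigned_regions(g, anchor="nad1")

    def test_urs_match_interval_complement_oracle(self, rng):
        for _ in range(20):
            L = int(rng.integers(200, 500))
            feats, pos = [], 0
            k = 0
            while pos < L - 40:
                gap = int(rng.integers(0, 25))
                glen = int(rng.integers(20, 60))
                s = pos + gap
                e = min(s + glen, L)
                if e <= s:
                    break
                name = "cox1" if k == 0 else f"g{k}"
                feats.append(GeneFeature(name=name, kind="other" if k else "PCG",
                                         start=s, end=e))
                pos = e
                k += 1
            g = AnnotatedGenome(id="R", organism="r", route="unknown",
                                sequence="A" * L, features=feats)
            urs = extract_unassigned_regions(g)
            oracle = _complement_intervals(L, [(f.start, f.end) for f in feats])
            # merge circular wrap in oracle the same way
            if len(oracle) > 1 and oracle[0][0] == 0 and oracle[-1][1] == L:
                first, last = oracle[0], oracle[-1]
                oracle = oracle[1:-1] + [(last[0], L + first[1])]
            assert sorted((u.start, u.end) for u in urs) == sorted(oracle)
            # partition property: features + URs tile [0, L) exactly once
            covered = np.zeros(L, dtype=int)
            for s, e in [(f.start, f.end) for f in feats] + \
                        [(u.start, u.end) for u in urs]:
                if e <= L:
                    covered[s:e] += 1
                else:
                    covered[s:] += 1
                    covered[: e - L] += 1
            assert (covered == 1).all()

    def test_numbering_invariant_under_rotation(self, ancestor_genome):
        g = ancestor_genome
        urs0 = extract_unassigned_regions(g)
        k = 4321
        seq = g.sequence[k:] + g.sequence[:k]
        feats = []
        for f in g.features:
            s = (f.start - k) % g.length
            feats.append(GeneFeature(name=f.name, kind=f.kind, start=s,
                                     end=s + f.length, strand=f.strand,
                                     copy_index=f.copy_index))
        rot = AnnotatedGenome(id=g.id, organism=g.organism, route=g.route,
                              sequence=seq, features=feats)
        urs1 = extract_unassigned_regions(rot)
        assert [u.sequence for u in urs0] == [u.sequence for u in urs1]
        assert [u.index for u in urs0] == [u.index for u in urs1]
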