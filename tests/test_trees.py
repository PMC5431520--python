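"""Neighbor joining and transmission-pattern classification."""

import numpy as np
import pytest

from mito_orfan.trees import (DistanceMatrix, LabelledTree, classify_pattern,
                              distance_matrix, neighbor_joining)

from oracles import (all_unrooted_topologies, canon_split, path_length_matrix,
                     tree_splits)


def dm(labels, values):
    return DistanceMatrix(labels=tuple(labels), values=np.array(values, float))


def nj_splits(tree):
    """Nontrivial bipartitions of an inferred tree, canonicalized."""
    tips = set(tree.tip_labels)
    out = set()
    for node in tree.tree.preorder_node_iter():
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if 2 <= len(side) <= len(tips) - 2:
            out.add(canon_split(side, tips))
    return out


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        t = neighbor_joining(dm("ABC", [[0, 2, 3], [2, 0, 3], [3, 3, 0]]))
        lengths = {l.taxon.label: l.edge.length for l in t.tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(1.0)
        assert lengths["C"] == pytest.approx(2.0)

    def test_four_taxon_additive_matrix_recovered(self):
        # tree ((A:1,B:2):1,(C:3,D:1)) with internal edge 1
        d = dm("ABCD", [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]])
        t = neighbor_joining(d)
        assert nj_splits(t) == {frozenset("AB")}
        # pendant lengths recovered on an additive input
        lengths = {l.taxon.label: l.edge.length for l in t.tree.leaf_node_iter()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_matches_scikit_bio_on_random_matrices(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj
        labels = [f"t{i}" for i in range(7)]
        for _ in range(10):
            base = rng.random((7, 7)) * 0.5 + 0.1
            m = (base + base.T) / 2
            np.fill_diagonal(m, 0)
            ours = neighbor_joining(dm(labels, m))
            theirs = sk_nj(SkDM(m, ids=labels))
            their_splits = set()
            for node in theirs.traverse():
                side = frozenset(t.name for t in node.tips())
                if 2 <= len(side) <= 5:
                    their_splits.add(side if len(side) * 2 <= 7
                                     else frozenset(set(labels) - side))
            assert nj_splits(ours) == their_splits

    def test_noisy_additive_matrices_recover_topology(self, rng):
        """>= 95% correct 8-taxon topologies at small distance noise."""
        tips = [f"t{i}" for i in range(8)]
        ok = 0
        reps = 100
        for _ in range(reps):
            # random additive tree via random topology + lengths
            edges = all_unrooted_topologies(tips[:6])[int(rng.integers(105))]
            # extend to 8 taxa by attaching to random edges
            nxt = -10
            for leaf in tips[6:]:
                i = int(rng.integers(len(edges)))
                u, v = edges[i]
                edges = edges[:i] + edges[i + 1:] + [(u, nxt), (nxt, v), (nxt, leaf)]
                nxt -= 1
            lengths = rng.uniform(0.05, 0.3, len(edges))
            d = path_length_matrix(edges, lengths, tips)
            noise = rng.normal(0, 0.005, d.shape)
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0)
            t = neighbor_joining(dm(tips, np.abs(d + noise)))
            if nj_splits(t) == tree_splits(edges, set(tips)):
                ok += 1
        assert ok / reps >= 0.95

    def test_negative_branch_lengths_clamped(self, caplog):
        d = dm("ABCD", [[0, .1, .4, .4], [.1, 0, .4, .4],
                        [.4, .4, 0, .01], [.4, .4, .01, 0]])
        with caplog.at_level("WARNING", logger="mito_orfan"):
            t = neighbor_joining(d)
        for leaf in t.tree.leaf_node_iter():
            assert leaf.edge.length >= 0

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            dm("AB", [[0, 1], [2, 0]])


class TestDistanceMatrix:
    def test_identical_pair_zero(self):
        d = distance_matrix({"a": "ACGT", "b": "ACGT", "c": "AGGT"})
        assert d.values[0, 1] == 0 and d.values[0, 2] == 0.25

    def test_pairwise_oracle(self, rng):
        from mito_orfan.divergence import p_distance
        seqs = {f"s{i}": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 50)])
                for i in range(4)}
        d = distance_matrix(seqs)
        for i, a in enumerate(seqs):
            for j, b in enumerate(seqs):
                assert d.values[i, j] == pytest.approx(p_distance(seqs[a], seqs[b]))

    def test_fm_blocks_near_generator_target(self, study):
        from mito_orfan.pipeline import pcg_concat_alignment
        genomes, truth = study
        aln = pcg_concat_alignment(genomes)
        d = distance_matrix(aln)
        labels = list(d.labels)
        for f_id, m_id in truth.fm_pairs:
            v = d.values[labels.index(f_id), labels.index(m_id)]
            assert v == pytest.approx(0.40, abs=0.02)


class TestClassifyPattern:
    def test_gender_joining_topology(self):
        t = LabelledTree.from_newick(
            "((A|F,B|F),(C|F,(A|M,(B|M,C|M))));")
        call = classify_pattern(t)
        assert call.pattern == "gender_joining"
        assert "A|M" in call.evidence

    def test_taxon_joining_topology(self):
        t = LabelledTree.from_newick(
            "((A|F,A|M),((B|F,B|M),(C|F,C|M)));")
        assert classify_pattern(t).pattern == "taxon_joining"

    def test_masculinized_tip_gives_mixed_with_violator(self):
        # B's F sits inside the M clade: neither pattern holds
        t = LabelledTree.from_newick(
            "((A|F,(B|F,C|F)),(A|M,(B|M,(B2|F,C|M))));".replace("B2|F", "D|F"))
        t2 = LabelledTree.from_newick(
            "((A|F,C|F),(A|M,(B|F,(B|M,C|M))));")
        call = classify_pattern(t2)
        assert call.pattern == "mixed"
        assert "B" in call.evidence

    def test_invariant_under_rerooting_and_tip_order(self):
        nwk = "((A|F,B|F),(C|F,(A|M,(B|M,C|M))));"
        base = classify_pattern(LabelledTree.from_newick(nwk)).pattern
        t = LabelledTree.from_newick(nwk)
        leaf = next(l for l in t.tree.leaf_node_iter() if l.taxon.label == "B|M")
        t.tree.reroot_at_edge(leaf.edge, update_bipartitions=True)
        assert classify_pattern(t).pattern == base
        nwk2 = "(((C|M,B|M),A|M),(C|F,(B|F,A|F)));"
        assert classify_pattern(LabelledTree.from_newick(nwk2)).pattern == base

    def test_h_tips_group_with_f(self):
        t = LabelledTree.from_newick(
            "((A|H,B|F),(C|F,(A|M,(B|M,C|M))));")
        assert classify_pattern(t).pattern == "gender_joining"

    def test_missing_route_raises(self):
        t = LabelledTree.from_newick("((A|F,B|F),(A|M,B|M));")
        del t.routes["A|M"]
        with pytest.raises(ValueError):
            classify_pattern(t)
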