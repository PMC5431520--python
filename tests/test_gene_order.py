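"""Gene-order algebra: breakpoints, TDRL, fragments, tandem repeats."""

import numpy as np
import pytest

from mito_orfan.gene_order import (GeneOrderPerm, breakpoint_distance,
                                   find_pseudogene_fragments,
                                   find_tandem_repeats, gene_order, replay_tdrl,
                                   tdrl_feasible)
from mito_orfan.genome import UnassignedRegion
from mito_orfan.simulate import _decay, _random_seq

from oracles import canon_circ, tdrl_reachable


def perm(tokens, circular=True):
    return GeneOrderPerm(tuple((str(abs(t)), 1 if t > 0 else -1) for t in tokens),
                         circular=circular)


class TestBreakpoints:
    def test_identical_orders_distance_zero(self):
        p = perm([1, 2, 3, 4])
        assert breakpoint_distance(p, p) == 0

    def test_signed_inversion_preserves_inverted_adjacency(self):
        # (1,2,3,4) vs (1,-3,-2,4): (2,3) survives as (-3,-2)
        assert breakpoint_distance(perm([1, 2, 3, 4]), perm([1, -3, -2, 4])) == 2

    def test_symmetric_on_random_permutations(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 9))
            a = perm(list(rng.permutation(np.arange(1, n + 1))))
            b = perm(list(rng.permutation(np.arange(1, n + 1))))
            assert breakpoint_distance(a, b) == breakpoint_distance(b, a)

    def test_invariant_under_rotation(self, rng):
        a = perm([1, 2, 3, 4, 5, 6])
        b = perm([2, 1, 4, 3, 6, 5])
        d = breakpoint_distance(a, b)
        for k in range(6):
            assert breakpoint_distance(a.rotate(k), b.rotate((k * 5) % 6)) == d

    def test_disjoint_token_sets_raise(self):
        with pytest.raises(ValueError):
            breakpoint_distance(perm([1, 2]), perm([3, 4]))

    def test_cox2_nad3_inversion_costs_two_adjacencies(self, study):
        genomes, _ = study
        g = genomes[0]
        order = gene_order(g)
        toks = list(order.tokens)
        i = order.names.index("cox2")
        assert order.names[i + 1] == "nad3"
        toks[i], toks[i + 1] = (toks[i + 1][0], -1), (toks[i][0], -1)
        inverted = GeneOrderPerm(tuple(toks), circular=True)
        assert breakpoint_distance(order, inverted) == 2


class TestTdrl:
    def test_identical_orders_trivially_feasible(self):
        p = perm([1, 2, 3], circular=False)
        ok, w, _ = tdrl_feasible(p, p)
        assert ok and w.block == ()

    def test_adjacent_swap_is_one_tdrl(self):
        ok, w, _ = tdrl_feasible(perm([1, 2, 3], circular=False),
                                 perm([2, 1, 3], circular=False))
        assert ok
        assert replay_tdrl(perm([1, 2, 3], circular=False), w).names == \
            ("2", "1", "3")

    def test_full_reversal_needs_more_than_one_tdrl(self):
        ok, w, reason = tdrl_feasible(perm([1, 2, 3], circular=False),
                                      perm([3, 2, 1], circular=False))
        assert not ok and w is None

    def test_sign_mismatch_is_infeasible_by_definition(self):
        ok, _, reason = tdrl_feasible(perm([1, 2, 3]), perm([1, -2, 3]))
        assert not ok and "invert" in reason

    def test_agrees_with_replay_oracle_linear_n5(self):
        from itertools import permutations
        reach = tdrl_reachable(5, circular=False)
        src = perm([1, 2, 3, 4, 5], circular=False)
        for p in permutations(range(5)):
            tgt = perm([x + 1 for x in p], circular=False)
            ok, w, _ = tdrl_feasible(src, tgt)
            assert ok == (p in reach), p
            if ok:
                assert replay_tdrl(src, w).names == tgt.names

    def test_agrees_with_replay_oracle_circular_n5(self):
        from itertools import permutations
        reach = tdrl_reachable(5, circular=True)
        src = perm([1, 2, 3, 4, 5])
        for p in permutations(range(5)):
            tgt = perm([x + 1 for x in p])
            ok, w, _ = tdrl_feasible(src, tgt)
            assert ok == (canon_circ(p) in reach), p
            if ok:
                got = replay_tdrl(src, w).canonical().names
                assert got == tgt.canonical().names

    def test_witness_replay_reproduces_target(self, rng):
        reach = sorted(tdrl_reachable(7, circular=False))
        src = perm(list(range(1, 8)), circular=False)
        for p in reach[:: max(1, len(reach) // 50)]:
            tgt = perm([x + 1 for x in p], circular=False)
            ok, w, _ = tdrl_feasible(src, tgt)
            assert ok
            assert replay_tdrl(src, w).names == tgt.names


class TestPseudogeneFragments:
    def make_ur(self, seq):
        return UnassignedRegion(genome_id="G", index=1, start=0, end=len(seq),
                                sequence=seq)

    def test_exact_substring_found_with_identity_one(self, rng):
        ref = _random_seq(rng, 150, 0.6)
        ur = self.make_ur(_random_seq(rng, 100, 0.6) + ref[40:70]
                          + _random_seq(rng, 100, 0.6))
        hits = find_pseudogene_fragments(ur, {"atp8": ref})
        # exact-match lower bound: the optimal local alignment spans the
        # planted block and scores at least its length (it may extend
        # further by chaining coincidental flank matches)
        assert any(h.query_id == "atp8" and h.score >= 30
                   and h.subject_start <= 100 and h.subject_end >= 130
                   for h in hits)

    def test_decayed_fragment_still_detected(self, rng):
        ref = _random_seq(rng, 165, 0.6)
        frag = _decay(rng, ref, 0.15)
        ur = self.make_ur(_random_seq(rng, 80, 0.6) + frag + _random_seq(rng, 80, 0.6))
        hits = find_pseudogene_fragments(ur, {"atp8": ref})
        assert any(h.query_id == "atp8" and h.subject_end - h.subject_start > 80
                   for h in hits)

    def test_reverse_strand_fragment_detected(self, rng):
        from Bio.Seq import Seq
        ref = _random_seq(rng, 120, 0.6)
        rc = str(Seq(ref).reverse_complement())
        ur = self.make_ur(_random_seq(rng, 60, 0.6) + rc + _random_seq(rng, 60, 0.6))
        hits = find_pseudogene_fragments(ur, {"nad6": ref})
        assert any(h.query_id == "nad6" for h in hits)

    def test_false_positive_rate_at_default_threshold(self, rng):
        """Random URs of matched composition stay below 5% false positives."""
        refs = {"atp8": _random_seq(rng, 165, 0.6), "trnD": _random_seq(rng, 66, 0.6)}
        n_fp = 0
        trials = 400
        for _ in range(trials):
            ur = self.make_ur(_random_seq(rng, 500, 0.6))
            if find_pseudogene_fragments(ur, refs):
                n_fp += 1
        assert n_fp / trials <= 0.05


class TestTandemRepeats:
    def test_exact_triplication(self, rng):
        unit = _random_seq(rng, 100, 0.6)
        seq = _random_seq(rng, 200, 0.6) + unit * 3 + _random_seq(rng, 200, 0.6)
        reps = find_tandem_repeats(seq, min_period=50)
        assert len(reps) == 1
        r = reps[0]
        assert r.period == 100 and r.mean_identity == 1.0
        assert r.copy_number == pytest.approx(3.0, abs=0.5)
        assert abs(r.start - 200) <= 100 and abs(r.end - 500) <= 100

    def test_repeat_free_sequence_reports_nothing(self, rng):
        assert find_tandem_repeats(_random_seq(rng, 300, 0.5), min_period=50) == []

    def test_decayed_copies_detected_above_identity_margin(self, rng):
        unit = _random_seq(rng, 120, 0.6)
        copies = unit + _decay(rng, unit, 0.08) + _decay(rng, unit, 0.08)
        seq = _random_seq(rng, 150, 0.6) + copies + _random_seq(rng, 150, 0.6)
        reps = find_tandem_repeats(seq, min_period=50, min_identity=0.8)
        assert any(abs(r.period - 120) <= 12 for r in reps)

    def test_smallest_period_reported_for_harmonics(self, rng):
        unit = _random_seq(rng, 60, 0.6)
        seq = unit * 6  # periods 60, 120, 180 all "fit"; 60 must win
        reps = find_tandem_repeats(seq, min_period=50)
        assert reps and reps[0].period == 60

    def test_span_consistency_invariant(self, rng):
        unit = _random_seq(rng, 80, 0.6)
        seq = _random_seq(rng, 100, 0.5) + unit * 4 + _random_seq(rng, 100, 0.5)
        for r in find_tandem_repeats(seq, min_period=50):
            assert abs((r.end - r.start) - r.period * r.copy_number) <= r.period
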