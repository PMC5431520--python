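"""Gene-order comparison: breakpoints, TDRL feasibility, repeats.

The M genome's tRNA-Asp/atp8 neighbourhood is rearranged relative to F.
A single tandem duplication-random loss (TDRL) — duplicate a contiguous
block, lose one copy of each gene — explains the change; the witness
says which copy each gene survived from, and replaying it reproduces
the M order exactly.  The decayed unretained copies remain detectable
in the unassigned regions, inside a large tandem repeat region.
"""

from mito_orfan import (SimConfig, simulate_study, gene_order,
                        breakpoint_distance, tdrl_feasible, replay_tdrl,
                        find_tandem_repeats, find_pseudogene_fragments,
                        extract_unassigned_regions)

genomes, truth = simulate_study(SimConfig(seed=1, n_species=1))
F, M = genomes[0], genomes[1]

fo, mo = gene_order(F), gene_order(M)
shared = set(fo.names) & set(mo.names)
src, tgt = fo.restrict(shared), mo.restrict(shared)

print("breakpoint distance F vs M:", breakpoint_distance(src, tgt))
ok, witness, reason = tdrl_feasible(src, tgt)
print("single TDRL feasible:", ok, "-", reason)
print("retained:", {g: c for g, c in sorted(witness.retained_from.items())
                    if g in ("trnD", "atp8")})
print("replay reproduces M order:",
      replay_tdrl(src, witness).canonical().tokens == tgt.canonical().tokens)

reps = find_tandem_repeats(M.sequence, min_period=50)
for r in reps:
    print(f"tandem repeat: {r.start}-{r.end}, period {r.period} bp, "
          f"{r.copy_number:.2f} copies, identity {r.mean_identity:.2f}")

refs = {"atp8": M.feature_seq(M.get("atp8"))}
for ur in extract_unassigned_regions(M):
    for h in find_pseudogene_fragments(ur, refs):
        print(f"decayed atp8 fragment in UR {ur.index}: "
              f"{ur.start + h.subject_start}-{ur.start + h.subject_end}, "
              f"score {h.score:.0f}, identity {h.identity:.2f}")
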