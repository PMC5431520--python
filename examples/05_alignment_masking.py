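"""Consensus alignment masking: keep columns backed by >= 3 of 4 maskers.

External maskers disagree about which alignment columns are noise; the
consensus rule retains a column only when at least k of n maskers keep
it.  Two built-in maskers (gap fraction and column entropy) plus two
synthetic verdicts stand in for four external programs here.
"""

from mito_orfan import SiteMask, builtin_masks, combine_masks, apply_mask

alignment = [
    "ATG-CGATTA",
    "ATGACGCTTA",
    "ATG-CGGTTA",
    "CTG-TTAT-A",
]

gap_mask, entropy_mask = builtin_masks(alignment, max_gap_fraction=0.3,
                                       max_entropy=1.0)
external_1 = SiteMask(source="ext1", keep=(1, 1, 1, 0, 1, 1, 0, 1, 1, 1))
external_2 = SiteMask(source="ext2", keep=(1, 1, 1, 0, 0, 1, 1, 0, 1, 1))

masks = [gap_mask, entropy_mask, external_1, external_2]
for m in masks:
    print(f"{m.source:>14}: {''.join('1' if k else '0' for k in m.keep)}")

consensus = combine_masks(masks, k=3)
print(f"{'consensus>=3':>14}: {''.join('1' if k else '0' for k in consensus.keep)}")
print(f"kept {consensus.n_kept}/{consensus.n_columns} columns")
for row in apply_mask(alignment, consensus):
    print(" ", row)
# A column kept by only 2 of the 4 maskers is discarded.
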