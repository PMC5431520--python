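"""Per-column alignment masks and the k-of-n consensus rule.

External alignment maskers emit heterogeneous per-column verdicts; this
module represents each as a :class:`SiteMask` (a boolean keep vector)
and combines them with the consensus rule used for phylogenetic
filtering: a column is retained iff at least k of the n maskers kept it
(default k=3, matching the three-out-of-four rule).  Two simple
built-in maskers (gap fraction and column Shannon entropy) make the
pipeline self-contained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger("mito_orfan")

__all__ = [
    "SiteMask",
    "combine_masks",
    "builtin_masks",
    "apply_mask",
    "read_mask",
    "write_mask",
]


@dataclass(frozen=True)
class SiteMask:
    source: str
    keep: tuple[bool, ...]

    @property
    def n_columns(self) -> int:
        return len(self.keep)

    @property
    def n_kept(self) -> int:
        return sum(self.keep)


def combine_masks(masks: list[SiteMask], k: int = 3) -> SiteMask:
    """Column kept iff kept by at least k sources.

    k=1 is the union, k=len(masks) the intersection.  k greater than
    the number of masks yields an all-drop mask with a warning.
    """
    if not masks:
        raise ValueError("need at least one mask")
    n = masks[0].n_columns
    if any(m.n_columns != n for m in masks):
        raise ValueError("masks differ in column count")
    if k > len(masks):
        logger.warning("k=%d exceeds number of masks (%d); empty result", k, len(masks))
        return SiteMask(source=f"consensus>={k}", keep=tuple([False] * n))
    votes = np.sum([m.keep for m in masks], axis=0)
    return SiteMask(source=f"consensus>={k}", keep=tuple(bool(v >= k) for v in votes))


def _column_entropy(column: str) -> float:
    """Shannon entropy (bits) over non-gap symbols; all-gap -> +inf."""
    symbols = [c for c in column if c != "-"]
    if not symbols:
        return math.inf
    counts: dict[str, int] = {}
    for c in symbols:
        counts[c] = counts.get(c, 0) + 1
    total = len(symbols)
    return -sum((c / total) * math.log2(c / total) for c in counts.values())


def builtin_masks(
    alignment: list[str], max_gap_fraction: float = 0.5, max_entropy: float = 1.5
) -> list[SiteMask]:
    """Two simple maskers: gap fraction <= g and column entropy <= h bits."""
    if not alignment:
        raise ValueError("empty alignment")
    n = len(alignment[0])
    if any(len(s) != n for s in alignment):
        raise ValueError("alignment is not rectangular")
    gap_keep, ent_keep = [], []
    rows = len(alignment)
    for j in range(n):
        col = "".join(s[j] for s in alignment)
        gap_keep.append(col.count("-") / rows <= max_gap_fraction)
        ent_keep.append(_column_entropy(col) <= max_entropy)
    return [
        SiteMask(source=f"gap<={max_gap_fraction}", keep=tuple(gap_keep)),
        SiteMask(source=f"entropy<={max_entropy}", keep=tuple(ent_keep)),
    ]


def apply_mask(alignment: list[str], mask: SiteMask) -> list[str]:
    """Concatenate the kept columns of each row, in order."""
    if not alignment:
        return []
    if len(alignment[0]) != mask.n_columns:
        raise ValueError(
            f"alignment has {len(alignment[0])} columns, mask {mask.n_columns}")
    idx = [j for j, keep in enumerate(mask.keep) if keep]
    return ["".join(s[j] for j in idx) for s in alignment]


def read_mask(path: str | Path, n_columns: int | None = None) -> SiteMask:
    """Read a mask file: a 0/1 string per column, or a whitespace list of
    kept 1-based column indices (requires n_columns)."""
    text = Path(path).read_text().strip()
    label = Path(path).stem
    tokens = text.split()
    if len(tokens) == 1 and set(tokens[0]) <= {"0", "1"}:
        return SiteMask(source=label, keep=tuple(c == "1" for c in tokens[0]))
    if n_columns is None:
        raise ValueError(f"{path}: index-list mask dialect needs n_columns")
    kept = {int(t) for t in tokens}
    if kept and (min(kept) < 1 or max(kept) > n_columns):
        raise ValueError(f"{path}: column index outside 1..{n_columns}")
    return SiteMask(source=label, keep=tuple((j + 1) in kept for j in range(n_columns)))


def write_mask(mask: SiteMask, path: str | Path) -> None:
    Path(path).write_text("".join("1" if k else "0" for k in mask.keep) + "\n")
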