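"""Pairwise alignment utilities used by the homology screen.

Local (Smith–Waterman) and global (Needleman–Wunsch) alignment with
affine gaps, configured the way the homology screen needs them:
BLOSUM62 with gap open 11 / extend 1 for proteins (a gap of length L
costs 11 + (L-1)), and +1/-1 with gap 2 per base for nucleotides.
The dynamic programming itself is delegated to
:class:`Bio.Align.PairwiseAligner`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "ScreenHit",
    "protein_aligner",
    "nucleotide_aligner",
    "smith_waterman",
    "needleman_wunsch",
]

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZX*")
NT_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class ScreenHit:
    """Best local alignment between a query and a subject sequence."""

    query_id: str
    subject_id: str
    score: float
    identity: float
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int

    @property
    def query_span(self) -> tuple[int, int]:
        return (self.query_start, self.query_end)

    @property
    def subject_span(self) -> tuple[int, int]:
        return (self.subject_start, self.subject_end)


def protein_aligner(mode: str = "local", open_: float = 11.0, extend: float = 1.0,
                    matrix: str = "BLOSUM62") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -open_
    aligner.extend_gap_score = -extend
    if mode == "global":
        # end gaps in a global protein alignment are free (semi-global),
        # appropriate for threading codon alignments of 3'-extended genes
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    return aligner


def nucleotide_aligner(mode: str = "local", match: float = 1.0, mismatch: float = -1.0,
                       gap: float = 2.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    alphabet = "ACGTN"
    m = np.full((5, 5), mismatch)
    np.fill_diagonal(m, match)
    # N never rewards a match (masked or ambiguous base)
    m[4, :] = mismatch
    m[:, 4] = mismatch
    aligner.substitution_matrix = substitution_matrices.Array(alphabet, 2, m)
    aligner.open_gap_score = -gap
    aligner.extend_gap_score = -gap
    return aligner


_DEFAULT_ALIGNERS: dict[tuple[str, bool], Align.PairwiseAligner] = {}


def _default_aligner(mode: str, is_protein: bool) -> Align.PairwiseAligner:
    key = (mode, is_protein)
    if key not in _DEFAULT_ALIGNERS:
        _DEFAULT_ALIGNERS[key] = (protein_aligner(mode) if is_protein
                                  else nucleotide_aligner(mode))
    return _DEFAULT_ALIGNERS[key]


def _check_alphabet(seq: str, is_protein: bool, label: str) -> None:
    alphabet = PROTEIN_ALPHABET if is_protein else NT_ALPHABET
    bad = set(seq) - alphabet
    if bad:
        raise ValueError(f"{label}: invalid symbols {sorted(bad)}")


def _hit_from_alignment(aln, query_id: str, subject_id: str) -> ScreenHit:
    a, b = aln[0], aln[1]
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    cols = sum(1 for x, y in zip(a, b) if x != "-" and y != "-")
    identity = matches / cols if cols else 0.0
    (qs, qe) = (int(aln.coordinates[0][0]), int(aln.coordinates[0][-1]))
    (ss, se) = (int(aln.coordinates[1][0]), int(aln.coordinates[1][-1]))
    return ScreenHit(
        query_id=query_id, subject_id=subject_id, score=float(aln.score),
        identity=identity, query_start=qs, query_end=qe,
        subject_start=ss, subject_end=se,
    )


def smith_waterman(
    a: str,
    b: str,
    *,
    is_protein: bool = True,
    threshold: float = 0.0,
    aligner: Align.PairwiseAligner | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> ScreenHit | None:
    """Optimal local alignment; returns a hit iff score >= threshold.

    ``a`` is the query, ``b`` the subject.  Defaults: BLOSUM62 gap 11/1
    for proteins, +1/-1 gap 2 for nucleotides.
    """
    if not a or not b:
        raise ValueError("smith_waterman requires non-empty sequences")
    _check_alphabet(a, is_protein, query_id)
    _check_alphabet(b, is_protein, subject_id)
    if aligner is None:
        aligner = _default_aligner("local", is_protein)
    alns = aligner.align(a, b)
    if len(alns) == 0:
        return None
    best = alns[0]
    if best.score < threshold:
        return None
    return _hit_from_alignment(best, query_id, subject_id)


def needleman_wunsch(
    a: str,
    b: str,
    *,
    is_protein: bool = True,
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[str, str, float]:
    """Global alignment; returns the two gapped sequences and the score."""
    if not a or not b:
        raise ValueError("needleman_wunsch requires non-empty sequences")
    _check_alphabet(a, is_protein, "a")
    _check_alphabet(b, is_protein, "b")
    if aligner is None:
        aligner = _default_aligner("global", is_protein)
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1]), float(aln.score)
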