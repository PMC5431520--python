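"""Gene-order algebra: signed circular permutations, breakpoint
distance, single-TDRL feasibility, pseudogene-fragment detection and
tandem-repeat scanning.

A tandem duplication–random loss (TDRL) event duplicates a contiguous
(circularly contiguous) block of genes in tandem and subsequently loses
one copy of each duplicated gene.  Reading the survivors left to right,
the genes retained from the first copy precede those retained from the
second, each group in original order — so a target order is reachable
from a source by a single TDRL iff, outside some block, the orders
agree and, inside it, the target is a concatenation of two
source-ordered subsequences.  The witness records the block and the
copy (first/second) each gene was retained from; replaying the
duplication+loss with the witness reproduces the target exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import nucleotide_aligner, smith_waterman, ScreenHit
from .genome import AnnotatedGenome, UnassignedRegion

__all__ = [
    "GeneOrderPerm",
    "TdrlWitness",
    "TandemRepeatAnnotation",
    "gene_order",
    "breakpoint_distance",
    "tdrl_feasible",
    "replay_tdrl",
    "find_pseudogene_fragments",
    "find_tandem_repeats",
]

SignedToken = tuple[str, int]  # (gene token, +1/-1)


@dataclass(frozen=True)
class GeneOrderPerm:
    """Signed (strand-aware) gene order, optionally circular."""

    tokens: tuple[SignedToken, ...]
    circular: bool = True

    def __post_init__(self) -> None:
        names = [t[0] for t in self.tokens]
        if len(names) != len(set(names)):
            raise ValueError("gene tokens must be unique after copy-indexing")

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(t[0] for t in self.tokens)

    def restrict(self, names: set[str]) -> "GeneOrderPerm":
        return GeneOrderPerm(tuple(t for t in self.tokens if t[0] in names), self.circular)

    def rotate(self, k: int) -> "GeneOrderPerm":
        k %= len(self.tokens)
        return GeneOrderPerm(self.tokens[k:] + self.tokens[:k], self.circular)

    def canonical(self) -> "GeneOrderPerm":
        """Rotation-invariant representative (circular orders only)."""
        if not self.circular or not self.tokens:
            return self
        best = min(range(len(self.tokens)), key=lambda k: self.rotate(k).tokens)
        return self.rotate(best)


def gene_order(genome: AnnotatedGenome, include: set[str] | None = None) -> GeneOrderPerm:
    """Gene-order permutation from annotated features, ascending start.

    ``include`` filters by feature kind (default: PCG, rRNA, tRNA,
    ORFan — pseudogene fragments and unknowns excluded).
    """
    if include is None:
        include = {"PCG", "rRNA", "tRNA", "ORFan"}
    toks = tuple(
        (f.token, 1 if f.strand == "+" else -1)
        for f in genome.features if f.kind in include
    )
    return GeneOrderPerm(toks, circular=genome.topology == "circular")


def _adjacencies(perm: GeneOrderPerm) -> set[frozenset]:
    """Canonical signed adjacency set; (x,y) is identified with (-y,-x)."""
    toks = perm.tokens
    pairs = list(zip(toks, toks[1:]))
    if perm.circular and len(toks) > 1:
        pairs.append((toks[-1], toks[0]))
    out = set()
    for (a, sa), (b, sb) in pairs:
        fwd = ((a, sa), (b, sb))
        rev = ((b, -sb), (a, -sa))
        out.add(frozenset((fwd, rev)) if fwd != rev else frozenset((fwd,)))
    return out


def breakpoint_distance(a: GeneOrderPerm, b: GeneOrderPerm) -> int:
    """Number of signed adjacencies of a absent from b (shared tokens only)."""
    shared = set(a.names) & set(b.names)
    if not shared:
        raise ValueError("gene orders share no tokens")
    ra, rb = a.restrict(shared), b.restrict(shared)
    adj_a, adj_b = _adjacencies(ra), _adjacencies(rb)
    return len(adj_a - adj_b)


# TDRL -----------------------------------------------------------------------


@dataclass(frozen=True)
class TdrlWitness:
    """One tandem-duplication–random-loss explanation of a rearrangement."""

    block: tuple[str, ...]  # duplicated genes, source order
    retained_from: dict[str, int] = field(hash=False, default_factory=dict)  # gene -> 1 | 2


def replay_tdrl(source: GeneOrderPerm, witness: TdrlWitness) -> GeneOrderPerm:
    """Apply duplication of the witness block + loss per the assignment."""
    names = list(source.names)
    if not witness.block:
        return source
    start = names.index(witness.block[0])
    blk = len(witness.block)
    rotated = source.rotate(start)
    if rotated.names[:blk] != witness.block:
        raise ValueError("witness block is not contiguous in source")
    block_toks = rotated.tokens[:blk]
    rest = rotated.tokens[blk:]
    copy1 = tuple(t for t in block_toks if witness.retained_from[t[0]] == 1)
    copy2 = tuple(t for t in block_toks if witness.retained_from[t[0]] == 2)
    out = GeneOrderPerm(copy1 + copy2 + rest, source.circular)
    return out.rotate(-start % len(out)) if source.circular else out


def tdrl_feasible(
    source: GeneOrderPerm, target: GeneOrderPerm
) -> tuple[bool, TdrlWitness | None, str]:
    """Is target reachable from source by one tandem duplication–random loss?

    Returns (feasible, witness, reason).  TDRL never inverts genes, so a
    sign mismatch on any shared gene is infeasible by definition.
    """
    if sorted(source.names) != sorted(target.names):
        return False, None, "token multisets differ"
    signs_s = dict(source.tokens)
    signs_t = dict(target.tokens)
    bad = [g for g in signs_s if signs_s[g] != signs_t[g]]
    if bad:
        return False, None, f"sign mismatch (TDRL cannot invert): {sorted(bad)}"

    n = len(source)
    if n == 0 or source.tokens == target.tokens:
        return True, TdrlWitness(block=(), retained_from={}), "orders identical"

    src_names = list(source.names)
    tgt = list(target.names)
    tpos = {g: i for i, g in enumerate(tgt)}
    circular = source.circular and target.circular

    def check_sigma(sigma: list[str], block: list[str]) -> TdrlWitness | None:
        """Witness iff sigma is a concatenation of two block-ordered
        increasing subsequences (at most one descent).  Ranks come from
        the block itself, which may wrap the circular origin."""
        bpos = {g: i for i, g in enumerate(block)}
        order = [bpos[g] for g in sigma]
        descents = [j + 1 for j in range(len(order) - 1) if order[j] > order[j + 1]]
        if len(descents) > 1:
            return None
        split = descents[0] if descents else 0
        retained = {g: (1 if j < split else 2) for j, g in enumerate(sigma)}
        return TdrlWitness(block=tuple(block), retained_from=retained)

    # smallest feasible block first: the witness then names the minimal
    # duplicated segment rather than a vacuous whole-genome duplication
    for blk in range(1, n + 1):
        for i in range(n if circular else 1):
            s_rot = src_names[i:] + src_names[:i]
            block, rest = s_rot[:blk], s_rot[blk:]
            if rest:
                # the block occupies the same circular span, so the rest
                # must follow it in the target; names are unique, so
                # exactly one target rotation can align rest[0]
                k = (tpos[rest[0]] - blk) % n
                if not circular and k != 0:
                    continue
                t = tgt[k:] + tgt[:k]
                if t[blk:] != rest:
                    continue
                w = check_sigma(t[:blk], block)
                if w:
                    return True, w, "single TDRL suffices"
            else:
                for k in range(n if circular else 1):
                    w = check_sigma(tgt[k:] + tgt[:k], block)
                    if w:
                        return True, w, "single TDRL suffices"
    return False, None, "no single tandem duplication-random loss explains the target"


# Pseudogene fragments -------------------------------------------------------


def find_pseudogene_fragments(
    ur: UnassignedRegion,
    reference_genes: dict[str, str],
    min_len: int = 20,
    threshold: float = 22.0,
    max_hits_per_ref: int = 8,
) -> list[ScreenHit]:
    """Local-alignment hits of reference genes inside a UR, both strands.

    Scoring is +1 match, -1 mismatch, gap -2.  The default score
    threshold (22) sits above the random local-alignment noise floor of
    AT-rich mitogenome URs (Monte-Carlo calibrated for a <=5%% per-UR
    false-positive rate) while a 15%%-decayed tRNA-sized fragment still
    scores about twice that; overlapping hits to the same reference are
    merged.
    Detected regions are masked with N and the scan repeated, so
    multiple decayed copies of the same gene are all reported.
    """
    from Bio.Seq import Seq

    aligner = nucleotide_aligner("local")
    hits: list[ScreenHit] = []
    for name, ref in reference_genes.items():
        ref = ref.upper()
        for strand, subject in (("+", ur.sequence.upper()),
                                ("-", str(Seq(ur.sequence).reverse_complement()))):
            work = subject
            for _ in range(max_hits_per_ref):
                hit = smith_waterman(ref, work, is_protein=False, threshold=threshold,
                                     aligner=aligner, query_id=name,
                                     subject_id=f"{ur.genome_id}_UR_{ur.index}")
                if hit is None or hit.subject_end - hit.subject_start < min_len:
                    break
                ss, se = hit.subject_start, hit.subject_end
                if strand == "-":
                    ss, se = len(subject) - hit.subject_end, len(subject) - hit.subject_start
                hits.append(ScreenHit(
                    query_id=name, subject_id=hit.subject_id, score=hit.score,
                    identity=hit.identity, query_start=hit.query_start,
                    query_end=hit.query_end, subject_start=ss, subject_end=se))
                work = work[:hit.subject_start] + "N" * (hit.subject_end - hit.subject_start) \
                    + work[hit.subject_end:]
    return _merge_overlapping(hits)


def _merge_overlapping(hits: list[ScreenHit]) -> list[ScreenHit]:
    """Merge overlapping subject spans of hits to the same reference."""
    by_ref: dict[str, list[ScreenHit]] = {}
    for h in hits:
        by_ref.setdefault(h.query_id, []).append(h)
    out: list[ScreenHit] = []
    for ref, group in by_ref.items():
        group.sort(key=lambda h: h.subject_start)
        cur = group[0]
        for h in group[1:]:
            if h.subject_start < cur.subject_end:
                cur = ScreenHit(
                    query_id=ref, subject_id=cur.subject_id,
                    score=max(cur.score, h.score),
                    identity=max(cur.identity, h.identity),
                    query_start=min(cur.query_start, h.query_start),
                    query_end=max(cur.query_end, h.query_end),
                    subject_start=cur.subject_start,
                    subject_end=max(cur.subject_end, h.subject_end))
            else:
                out.append(cur)
                cur = h
        out.append(cur)
    out.sort(key=lambda h: (h.subject_start, h.query_id))
    return out


# Tandem repeats -------------------------------------------------------------


@dataclass(frozen=True)
class TandemRepeatAnnotation:
    start: int
    end: int
    period: int
    copy_number: float
    mean_identity: float


def find_tandem_repeats(
    seq: str,
    min_period: int = 50,
    max_period: int | None = None,
    min_copies: float = 2.0,
    min_identity: float = 0.8,
) -> list[TandemRepeatAnnotation]:
    """Periodicity scan for tandem repeats.

    For each candidate period p, positions where the window [i, i+p)
    matches [i+p, i+2p) at >= min_identity are merged into runs; a run
    supporting [a, b] yields a repeat region [a, b+2p) with copy number
    (b + 2p - a)/p.  Smallest periods are scanned first and larger-period
    harmonics overlapping an accepted region are suppressed.
    """
    seq = seq.upper()
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    if max_period is None:
        max_period = n // 2
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    accepted: list[TandemRepeatAnnotation] = []
    for p in range(min_period, max_period + 1):
        if 2 * p > n:
            break
        match = (arr[:-p] == arr[p:]).astype(np.int32)  # length n-p
        cs = np.concatenate(([0], np.cumsum(match)))
        limit = n - 2 * p + 1  # last i with full window
        if limit <= 0:
            continue
        ident = (cs[p:p + limit] - cs[:limit]) / p
        support = ident >= min_identity
        if not support.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], support.view(np.int8), [0]))))
        for a, b in zip(edges[::2], edges[1::2]):
            start, end = int(a), int(b - 1 + 2 * p)
            # trim to the matching core: windowed support bleeds up to
            # (1 - min_identity) * p into the random flanks, where only
            # short coincidental match runs occur
            k = min(8, p)
            while start < end - p - k and not match[start:start + k].all():
                start += 1
            while end - p - k > start and not match[end - p - k:end - p].all():
                end -= 1
            copies = (end - start) / p
            if copies + 1e-9 < min_copies:
                continue
            region = TandemRepeatAnnotation(
                start=start, end=end, period=p, copy_number=round(copies, 3),
                mean_identity=float(np.mean(match[start:end - p])))
            if any(_overlap(region, r) > 0.5 for r in accepted):
                continue  # harmonic or rediscovery of a smaller-period repeat
            accepted.append(region)
    accepted.sort(key=lambda r: r.start)
    return accepted


def _overlap(a: TandemRepeatAnnotation, b: TandemRepeatAnnotation) -> float:
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    return inter / max(1, (a.end - a.start))
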