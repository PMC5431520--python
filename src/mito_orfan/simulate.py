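"""Synthetic palaeoheterodont-like mitogenome generator with known truth.

Builds circular ~16 kb mitogenomes carrying the standard 37 mitochondrial
genes in a unionid-like order, then evolves F/M genome pairs to a
controlled nucleotide divergence and dN/dS, and plants the hallmark
features of DUI freshwater-mussel M genomes: a 3' in-frame cox2
extension, an M-orf between nad4L and tRNA-Asp, extra unannotated ORFs
in unassigned regions, a single tandem duplication–random loss (TDRL)
of the tRNA-Asp/atp8 block with decayed pseudogene remnants, and a
large tandem repeat region.  Every planted feature is recorded in a
:class:`SyntheticTruth` so the analysis stages can be validated
end-to-end.

The substitution machinery is deliberately simple and verifiable: one
seeded generator threaded through all steps; uniform per-site proposals
(configurable transition/transversion ratio), nonsynonymous proposals
accepted with probability omega, stop codons never created, no indels
inside genes.  Divergence targets are enforced by construction — a
lineage is mutated until the observed proportion of differing PCG sites
reaches the target.

Unassigned regions are "sterilized" after planting: any ORF the census
would find that was not deliberately planted is disrupted by an
in-frame premature stop codon, so the planted ORF inventory is exactly
the census truth.
"""

from __future__ import annotations

import math
from copy import deepcopy
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import AnnotatedGenome, GeneFeature, extract_unassigned_regions, write_genbank
from .gene_order import TdrlWitness
from .orfs import _codon_table, find_orfs

__all__ = ["SimConfig", "SyntheticTruth", "Segment", "GenomeBuilder",
           "make_ancestor", "evolve_pair", "plant_features", "simulate_study"]


# Template gene order (unionid-like F arrangement): cox1 first, the
# nad4L–trnD–atp8–nad6–atp6 neighbourhood that the TDRL rearranges, and
# no trailing spacer so the control region (upstream of cox1) is UR 1.
TEMPLATE_ORDER = (
    "cox1", "trnI", "trnS1", "nad2", "trnM", "trnC", "trnY", "cox2", "nad3",
    "trnA", "trnN", "trnE", "trnG", "cox3", "trnQ", "nad1", "trnL1", "trnL2",
    "nad4L", "trnD", "atp8", "nad6", "atp6", "trnR", "trnK", "trnW", "rrnL",
    "trnT", "trnH", "nad5", "trnF", "nad4", "trnP", "trnV", "rrnS", "trnS2",
    "cytb",
)

PCG_LENGTHS = {
    "cox1": 1536, "cox2": 690, "cox3": 786, "cytb": 1140, "nad1": 936,
    "nad2": 978, "nad3": 354, "nad4": 1341, "nad4L": 297, "nad5": 1719,
    "nad6": 501, "atp6": 708, "atp8": 165,
}
TRNA_LENGTH = 66
RRNA_LENGTHS = {"rrnS": 840, "rrnL": 1260}


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults emulate the divergence regime reported for DUI freshwater
    mussels: F-vs-M concatenated PCG p-distance 0.40 with dN/dS 0.33,
    a ~0.5 kb in-frame M-cox2 3' extension, three ~320 bp tandem repeat
    copies, and a TDRL of the tRNA-Asp/atp8 block with 15% pseudogene
    decay.
    """

    seed: int = 0
    n_species: int = 3
    target_p_nt: float = 0.40
    target_omega: float = 0.33
    kappa: float = 1.0  # transition/transversion ratio of the proposal kernel
    at_fraction: float = 0.60
    species_divergence: float = 0.03
    cox2_extension: int = 501  # bp, in-frame (multiple of 3)
    f_orf_codons: int = 60
    m_orf_codons: int = 90
    n_ur_orfs: int = 2  # extra planted ORFs in the control region, per genome
    ur_orf_codons: tuple[int, ...] = (12, 40)
    plant_m_orf2: bool = True  # extra UR ORF next to the rearranged atp8
    m_orf2_codons: int = 25
    tdrl: bool = True
    tdrl_decay: float = 0.15
    repeat_unit: int = 320
    repeat_copies: int = 3
    repeat_decay: float = 0.02
    control_region: int = 800
    spacer_range: tuple[int, int] = (5, 30)
    pattern: str = "gender_joining"  # or taxon_joining
    include_h: bool = False

    def __post_init__(self) -> None:
        for r in (self.target_p_nt, self.tdrl_decay, self.repeat_decay,
                  self.species_divergence):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.target_p_nt >= 0.75:
            raise ValueError("target p >= 0.75 is unreachable under the JC cap")
        if self.cox2_extension % 3:
            raise ValueError("cox2_extension must be a multiple of 3 (in-frame)")
        if self.pattern not in ("gender_joining", "taxon_joining"):
            raise ValueError(f"unknown pattern {self.pattern!r}")


@dataclass
class Segment:
    """One building block of a genome: a gene, a spacer, or planted UR content."""

    seq: str
    name: str | None = None
    kind: str | None = None  # feature kind when emitted
    strand: str = "+"
    coding: bool = False  # evolve under codon constraints
    emit: bool = False  # becomes an annotated GeneFeature
    tag: str | None = None  # truth bookkeeping
    regen: bool = False  # ORF-free spacer, regenerated per emitted genome


@dataclass
class GenomeBuilder:
    segments: list[Segment]

    def copy(self) -> "GenomeBuilder":
        return GenomeBuilder([dc_replace(s) for s in self.segments])

    def index_of(self, name: str) -> int:
        for i, s in enumerate(self.segments):
            if s.name == name:
                return i
        raise KeyError(name)

    def assemble(self, id: str, organism: str, route: str
                 ) -> tuple[AnnotatedGenome, dict[str, tuple[int, int]]]:
        """Concatenate segments into a genome; returns tag -> span map."""
        seq_parts: list[str] = []
        feats: list[GeneFeature] = []
        spans: dict[str, tuple[int, int]] = {}
        offset = 0
        counts: dict[str, int] = {}
        for s in self.segments:
            end = offset + len(s.seq)
            if s.tag:
                spans[s.tag] = (offset, end)
            if s.emit:
                counts[s.name] = counts.get(s.name, 0) + 1
                feats.append(GeneFeature(
                    name=s.name, kind=s.kind, start=offset, end=end,
                    strand=s.strand, copy_index=counts[s.name]))
            seq_parts.append(s.seq)
            offset = end
        genome = AnnotatedGenome(id=id, organism=organism, route=route,
                                 sequence="".join(seq_parts), features=feats)
        return genome, spans


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated study."""

    pattern: str
    fm_pairs: list[tuple[str, str]] = field(default_factory=list)
    planted_orfs: dict[str, list[dict]] = field(default_factory=dict)
    tdrl_witness: dict[str, TdrlWitness] = field(default_factory=dict)
    repeats: dict[str, list[dict]] = field(default_factory=dict)
    pseudogene_fragments: dict[str, list[dict]] = field(default_factory=dict)
    routes: dict[str, str] = field(default_factory=dict)
    species: dict[str, str] = field(default_factory=dict)


# sequence generation --------------------------------------------------------


def _base_probs(at: float) -> np.ndarray:
    return np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])  # A C G T


_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int, at: float) -> str:
    return "".join(_BASES[rng.choice(4, size=n, p=_base_probs(at))])


def _sense_codons(table: int) -> list[str]:
    return sorted(_codon_table(table).forward_table)


def _sample_codons(rng: np.random.Generator, n: int, at: float, table: int = 5) -> list[str]:
    codons = _sense_codons(table)
    probs = _base_probs(at)
    lut = {b: probs[i] for i, b in enumerate("ACGT")}
    w = np.array([lut[c[0]] * lut[c[1]] * lut[c[2]] for c in codons])
    w /= w.sum()
    return [codons[i] for i in rng.choice(len(codons), size=n, p=w)]


def _make_cds(rng: np.random.Generator, length: int, at: float, table: int = 5) -> str:
    assert length % 3 == 0 and length >= 9
    body = _sample_codons(rng, length // 3 - 2, at, table)
    return "ATG" + "".join(body) + "TAA"


def _has_orf(seq: str, min_codons: int = 10) -> bool:
    from .genome import UnassignedRegion

    ur = UnassignedRegion(genome_id="x", index=1, start=0, end=len(seq), sequence=seq)
    return bool(find_orfs(ur, min_codons=min_codons))


def _orf_free_seq(rng: np.random.Generator, n: int, at: float) -> str:
    """Random spacer sequence guaranteed to contain no ORF of >= 10 codons.

    Built in small chunks seeded with stop-codon motifs (TAATTA carries
    a stop on both strands) and verified as it grows; a chunk that lets
    an ORF form is resampled.  Truncation at the end cannot create an
    ORF.  The result is aperiodic, so it never registers as a tandem
    repeat.
    """
    if n == 0:
        return ""

    def chunk() -> str:
        # stop codons in all three frames on both strands: TAA staggered
        # by one base covers every forward frame, TTA every reverse frame
        r = lambda k: _random_seq(rng, int(rng.integers(1, k)), at)
        fwd = "TAA" + r(3)[:1] + "TAA" + r(3)[:1] + "TAA"
        rev = "TTA" + r(3)[:1] + "TTA" + r(3)[:1] + "TTA"
        return r(4) + fwd + r(4) + rev + r(4)

    # verified inside guard context: guards are the most permissive
    # neighbourhood a UR spacer can have (gene boundaries only remove
    # ORF opportunities), so the spacer stays clean wherever it lands.
    # No truncation: shortening could resurrect a boundary-crossing ORF.
    seq = ""
    while len(seq) < n:
        for _ in range(300):
            cand = seq + chunk()
            if not _has_orf(GUARD + cand + GUARD):
                seq = cand
                break
        else:
            raise RuntimeError("could not extend ORF-free spacer")
    return seq


def _decay(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            alt = [b for b in "ACGT" if b != out[i]]
            out[i] = alt[rng.integers(3)]
    return "".join(out)


# evolution ------------------------------------------------------------------

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _propose_base(rng: np.random.Generator, base: str, kappa: float) -> str:
    if rng.random() < kappa / (kappa + 2.0):
        return _TRANSITION[base]
    tv = [b for b in "ACGT" if b != base and b != _TRANSITION[base]]
    return tv[rng.integers(2)]


def _jc_lambda(p: float) -> float:
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def _evolve_noncoding(rng: np.random.Generator, seq: str, extra_p: float,
                      kappa: float) -> str:
    """Apply Poisson(lambda)-many substitutions per site for target p."""
    if extra_p <= 0:
        return seq
    lam = _jc_lambda(extra_p)
    out = list(seq)
    hits = rng.poisson(lam, size=len(out))
    for i in np.flatnonzero(hits):
        for _ in range(hits[i]):
            if out[i] in _TRANSITION:
                out[i] = _propose_base(rng, out[i], kappa)
    return "".join(out)


def _evolve_builder(
    rng: np.random.Generator,
    builder: GenomeBuilder,
    target_p: float,
    omega: float,
    kappa: float,
    ref: GenomeBuilder | None = None,
    noncoding_p: float | None = None,
    max_proposals: int = 5_000_000,
) -> None:
    """Mutate the builder in place until observed PCG p-distance vs the
    reference reaches target_p; nonsynonymous proposals accepted with
    probability omega, stops never created, first codons protected."""
    t = _codon_table(5)
    stops = set(t.stop_codons)
    fwd = t.forward_table

    coding_idx = [i for i, s in enumerate(builder.segments) if s.coding]
    pcg_idx = [i for i in coding_idx if builder.segments[i].kind == "PCG"]
    if not pcg_idx:
        raise ValueError("builder has no protein-coding genes to evolve")
    ref_segs = builder if ref is None else ref
    seqs = {i: list(builder.segments[i].seq) for i in coding_idx}
    refs = {i: ref_segs.segments[i].seq for i in coding_idx}
    for i in coding_idx:
        if len(seqs[i]) != len(refs[i]):
            raise ValueError("reference builder structure differs")

    pcg_sites = sum(len(seqs[i]) for i in pcg_idx)
    diffs = sum(
        1 for i in pcg_idx for a, b in zip(seqs[i], refs[i]) if a != b)
    lens = np.array([len(seqs[i]) for i in coding_idx], dtype=float)
    seg_p = lens / lens.sum()

    if target_p > 0:
        for _ in range(max_proposals):
            if diffs / pcg_sites >= target_p:
                break
            i = coding_idx[rng.choice(len(coding_idx), p=seg_p)]
            s = seqs[i]
            pos = int(rng.integers(len(s)))
            ci = pos - pos % 3
            if ci == 0:
                continue  # keep the start codon intact
            old = s[pos]
            new = _propose_base(rng, old, kappa)
            codon_old = "".join(s[ci:ci + 3])
            if codon_old in stops:
                continue  # a planted ORF's terminal stop stays put
            codon_new = codon_old[: pos - ci] + new + codon_old[pos - ci + 1:]
            if codon_new in stops:
                continue
            if fwd[codon_new] != fwd[codon_old] and rng.random() >= omega:
                continue
            s[pos] = new
            if i in pcg_idx:
                r = refs[i][pos]
                diffs += (new != r) - (old != r)
        else:
            raise RuntimeError("divergence target not reached (proposal cap)")

    for i in coding_idx:
        builder.segments[i].seq = "".join(seqs[i])
    nc_p = target_p if noncoding_p is None else noncoding_p
    if nc_p > 0:
        for s in builder.segments:
            if not s.coding and not s.regen:  # regen spacers are rebuilt at emit
                s.seq = _evolve_noncoding(rng, s.seq, nc_p, kappa)


# ancestor and planting ------------------------------------------------------


def make_ancestor(config: SimConfig, rng: np.random.Generator | None = None
                  ) -> GenomeBuilder:
    """37-gene circular template with random intergenic spacers.

    The control region (the UR upstream of cox1) leads the assembly, so
    it is UR number 1 and nothing wraps the origin.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    at = config.at_fraction
    segs: list[Segment] = [
        Segment(seq=_random_seq(rng, config.control_region, at),
                tag="control_region", regen=True)
    ]
    lo, hi = config.spacer_range
    for i, name in enumerate(TEMPLATE_ORDER):
        if name in PCG_LENGTHS:
            seq, kind, coding = _make_cds(rng, PCG_LENGTHS[name], at), "PCG", True
        elif name in RRNA_LENGTHS:
            seq, kind, coding = _random_seq(rng, RRNA_LENGTHS[name], at), "rRNA", False
        else:
            seq, kind, coding = _random_seq(rng, TRNA_LENGTH, at), "tRNA", False
        segs.append(Segment(seq=seq, name=name, kind=kind, coding=coding, emit=True))
        if i < len(TEMPLATE_ORDER) - 1:
            segs.append(Segment(seq=_random_seq(rng, int(rng.integers(lo, hi + 1)), at),
                                regen=True))
    return GenomeBuilder(segs)


# Guard motif flanking planted UR ORFs: stop codons in every frame on
# both strands (TAG staggered by one base; CTA is the reverse-strand
# stop) and no start codon in any frame, so no reading frame can run
# across a planted ORF's boundary.
GUARD = "TAGCTAGCTAGCTAG"


def _block_orfs(block: str) -> list:
    """All ORFs of a guarded planted block (local by guard construction)."""
    from .genome import UnassignedRegion

    ur = UnassignedRegion(genome_id="x", index=1, start=0, end=len(block),
                          sequence=block)
    return find_orfs(ur, min_codons=10)


def _make_planted_orf(rng: np.random.Generator, codons: int, at: float
                      ) -> tuple[str, list]:
    """A UR ORF plus the full local ORF inventory of its guarded block.

    The primary ORF spans the whole insert; nested or antisense ORFs
    that random coding sequence inevitably contains are enumerated here
    — the guards make them a purely local function of the block, so
    they form part of the planted truth.
    """
    for _ in range(500):
        nt = _make_cds(rng, 3 * (codons + 1), at)
        calls = _block_orfs(GUARD + nt + GUARD)
        if any(c.start == len(GUARD) and c.end == len(GUARD) + len(nt)
               and c.strand == "+" for c in calls):
            return nt, calls
    raise RuntimeError("could not sample a planted ORF")


def _guarded_body(seq: str, tag: str, **kwargs) -> tuple[list[Segment], list]:
    """Wrap UR content in guards and enumerate its (local) ORF inventory.

    Used both for deliberately planted ORFs and for content that
    incidentally contains ORFs (decayed pseudogene copies, tandem
    repeats) — exactly as real mitogenome repeats harbour ORFs over
    pseudogenized gene fragments.
    """
    calls = _block_orfs(GUARD + seq + GUARD)
    segs = [
        Segment(seq=GUARD, tag=f"{tag}!guardL"),
        Segment(seq=seq, tag=tag, **kwargs),
        Segment(seq=GUARD, tag=f"{tag}!guardR"),
    ]
    return segs, calls


def _guarded_orf(rng: np.random.Generator, codons: int, at: float,
                 tag: str) -> tuple[list[Segment], list]:
    nt, calls = _make_planted_orf(rng, codons, at)
    segs, _ = _guarded_body(nt, tag)
    return segs, calls


def _plant_ur_orfs(rng: np.random.Generator, builder: GenomeBuilder,
                   config: SimConfig) -> dict[str, list]:
    """Split the control region and embed the configured planted ORFs."""
    n = config.n_ur_orfs
    if n == 0:
        return {}
    idx = next(i for i, s in enumerate(builder.segments) if s.tag == "control_region")
    cr = builder.segments[idx].seq
    pieces = []
    calls_by_tag: dict[str, list] = {}
    chunk = len(cr) // (n + 1)
    for k in range(n):
        codons = config.ur_orf_codons[k % len(config.ur_orf_codons)]
        pieces.append(Segment(seq=cr[k * chunk:(k + 1) * chunk], regen=True))
        segs, calls = _guarded_orf(rng, codons, config.at_fraction,
                                   f"planted_orf_{k + 1}")
        pieces.extend(segs)
        calls_by_tag[f"planted_orf_{k + 1}"] = calls
    pieces.append(Segment(seq=cr[n * chunk:], tag="control_region", regen=True))
    builder.segments[idx:idx + 1] = pieces
    return calls_by_tag


def evolve_pair(
    ancestor: GenomeBuilder,
    target_p_nt: float,
    target_omega: float,
    seed: int,
    kappa: float = 1.0,
) -> tuple[GenomeBuilder, GenomeBuilder]:
    """(F, M) builders: F is the ancestor, M is evolved to the target
    concatenated PCG p-distance with dN/dS controlled by accept/reject."""
    rng = np.random.default_rng(seed)
    F = ancestor.copy()
    M = ancestor.copy()
    _evolve_builder(rng, M, target_p_nt, target_omega, kappa, ref=F)
    return F, M


def plant_features(
    M: GenomeBuilder, config: SimConfig, rng: np.random.Generator
) -> tuple[GenomeBuilder, dict]:
    """Add the M-genome hallmarks: cox2 3' extension, M-orf between
    nad4L and tRNA-Asp, optional second UR ORF beside the rearranged
    atp8, the TDRL of the tRNA-Asp/atp8 block with decayed remnants,
    and a tandem repeat region between nad6 and atp6."""
    at = config.at_fraction
    truth: dict = {}
    M = M.copy()

    if config.cox2_extension:
        i = M.index_of("cox2")
        seq = M.segments[i].seq
        ext = "".join(_sample_codons(rng, config.cox2_extension // 3, at))
        M.segments[i].seq = seq[:-3] + ext + seq[-3:]
        truth["cox2_length"] = len(M.segments[i].seq)

    # M-orf between nad4L and trnD
    i = M.index_of("trnD")
    m_orf = Segment(seq=_make_cds(rng, 3 * (config.m_orf_codons + 1), at),
                    name="M-orf", kind="ORFan", coding=True, emit=True, tag="M-orf")
    spacer = Segment(seq=_random_seq(rng, 10, at), regen=True)
    M.segments[i:i] = [m_orf, spacer]

    if config.tdrl:
        # duplicate the (trnD, atp8) block in tandem; keep atp8 from the
        # first copy and trnD from the second; remnants decay in place
        i_d, i_a = M.index_of("trnD"), M.index_of("atp8")
        assert i_a == i_d + 2  # trnD, spacer, atp8
        trnD, mid, atp8 = M.segments[i_d], M.segments[i_d + 1], M.segments[i_a]
        calls_out = truth.setdefault("planted_calls", {})
        psi_d, calls = _guarded_body(_decay(rng, trnD.seq, config.tdrl_decay),
                                     "psi_trnD")
        calls_out["psi_trnD"] = calls
        psi_a, calls = _guarded_body(_decay(rng, atp8.seq, config.tdrl_decay),
                                     "psi_atp8")
        calls_out["psi_atp8"] = calls
        mid2 = Segment(seq=_random_seq(rng, len(mid.seq), at), regen=True)
        new_block = psi_d + [dc_replace(mid), atp8]
        if config.plant_m_orf2:
            segs, calls = _guarded_orf(rng, config.m_orf2_codons, at,
                                       "planted_m_orf2")
            calls_out["planted_m_orf2"] = calls
            new_block += [mid2] + segs + [Segment(seq=_random_seq(rng, 8, at),
                                                  regen=True)]
        else:
            new_block += [mid2]
        new_block += [trnD] + psi_a
        M.segments[i_d:i_a + 1] = new_block
        truth["tdrl_witness"] = TdrlWitness(
            block=("trnD", "atp8"), retained_from={"atp8": 1, "trnD": 2})
        truth["pseudogene_fragments"] = [
            {"gene": "trnD", "tag": "psi_trnD", "decay": config.tdrl_decay},
            {"gene": "atp8", "tag": "psi_atp8", "decay": config.tdrl_decay},
        ]

    if config.repeat_copies >= 2:
        unit = _random_seq(rng, config.repeat_unit, at)
        copies = [unit] + [
            _decay(rng, unit, config.repeat_decay)
            for _ in range(config.repeat_copies - 1)
        ]
        rep, calls = _guarded_body("".join(copies), "tandem_repeat")
        truth.setdefault("planted_calls", {})["tandem_repeat"] = calls
        i = M.index_of("nad6")
        M.segments[i + 1:i + 1] = rep
        truth["repeat"] = {"period": config.repeat_unit,
                           "copies": config.repeat_copies}
    return M, truth


# sterilization --------------------------------------------------------------


def _sterilize(
    genome: AnnotatedGenome,
    protected: list[tuple[int, int]],
    allowed: set[tuple[int, int, str]],
    rng: np.random.Generator,
    max_rounds: int = 60,
) -> AnnotatedGenome:
    """Disrupt every UR ORF outside the planted inventory.

    ``protected`` spans (the guarded planted blocks) are never edited;
    ``allowed`` lists the exact (start, end, strand) ORFs of the truth.
    """
    seq = list(genome.sequence)
    prot = sorted(protected)

    def overlaps_protected(s: int, e: int) -> bool:
        return any(s < pe and ps < e for ps, pe in prot)

    for _ in range(max_rounds):
        g = AnnotatedGenome(id=genome.id, organism=genome.organism,
                            route=genome.route, sequence="".join(seq),
                            features=list(genome.features),
                            topology=genome.topology)
        bad: list[tuple[int, int, str]] = []
        for ur in extract_unassigned_regions(g):
            for orf in find_orfs(ur, min_codons=10):
                s, e = ur.start + orf.start, ur.start + orf.end
                if (s, e, orf.strand) in allowed:
                    continue
                bad.append((s, e, orf.strand))
        if not bad:
            return g
        for s, e, strand in bad:
            if strand == "+":
                frames = [(p, "TAA") for p in range(s + 3, e - 3, 3)]
            else:
                frames = [(p, "TTA") for p in range(e - 6, s, -3)]
            options = [(p, stop) for p, stop in frames
                       if not overlaps_protected(p, p + 3)]
            if not options:
                # fall back to rewriting the start codon
                p = s if strand == "+" else e - 3
                if overlaps_protected(p, p + 3):
                    continue
                options = [(p, "CAA" if strand == "+" else "TTG")]
            # saturate: a stop every ~4 codons, so split products stay short
            for p, codon in options[:: 4] or [options[0]]:
                seq[p:p + 3] = list(codon)
    raise RuntimeError(f"{genome.id}: UR sterilization did not converge")


def _finalize(
    builder: GenomeBuilder,
    id: str,
    organism: str,
    route: str,
    rng: np.random.Generator,
    truth: SyntheticTruth,
    planted_meta: dict | None = None,
    config: SimConfig | None = None,
) -> AnnotatedGenome:
    at = config.at_fraction if config else 0.60
    meta = planted_meta or {}
    calls_by_tag: dict[str, list] = dict(meta.get("planted_calls", {}))
    if config is not None:
        calls_by_tag.update(_plant_ur_orfs(rng, builder, config))
    for s in builder.segments:
        if s.regen:
            s.seq = _orf_free_seq(rng, len(s.seq), at)
    genome, spans = builder.assemble(id, organism, route)

    # guarded planted blocks are untouchable; their local ORF inventory
    # (primary + nested) is the allowed truth set
    protected: list[tuple[int, int]] = []
    allowed: set[tuple[int, int, str]] = set()
    planted: list[dict] = []
    for tag, calls in sorted(calls_by_tag.items()):
        bs = spans[f"{tag}!guardL"][0]
        be = spans[f"{tag}!guardR"][1]
        protected.append((bs, be))
        for c in calls:
            allowed.add((bs + c.start, bs + c.end, c.strand))
            planted.append({"tag": tag, "start": bs + c.start, "end": bs + c.end,
                            "strand": c.strand, "nt_length": c.nt_length,
                            "primary": (bs + c.start, bs + c.end) == spans[tag]})
    genome = _sterilize(genome, protected, allowed, rng)
    planted.sort(key=lambda d: (d["start"], d["end"]))
    truth.planted_orfs[id] = planted
    truth.routes[id] = route
    truth.species[id] = organism
    meta = planted_meta or {}
    if "tdrl_witness" in meta:
        truth.tdrl_witness[id] = meta["tdrl_witness"]
    if "repeat" in meta:
        rs, re_ = spans["tandem_repeat"]
        truth.repeats[id] = [{"start": rs, "end": re_, **meta["repeat"]}]
    if "pseudogene_fragments" in meta:
        frags = []
        for fr in meta["pseudogene_fragments"]:
            fs, fe = spans[fr["tag"]]
            frags.append({**fr, "start": fs, "end": fe})
        truth.pseudogene_fragments[id] = frags
    return genome


# whole-study simulation -----------------------------------------------------


def _compose_p(p: float, q: float) -> float:
    """Observed p-distance of two branches in series (JC composition)."""
    return p + q - (4.0 / 3.0) * p * q


def simulate_study(
    config: SimConfig, out_dir: str | Path | None = None
) -> tuple[list[AnnotatedGenome], SyntheticTruth]:
    """Simulate a multi-species F/M study with known transmission pattern.

    gender_joining: all M genomes descend from one M ancestor that split
    from the F lineage at deep divergence; taxon_joining: each species'
    M arises independently from that species' F (recurrent
    masculinization).  Within every species the F-vs-M concatenated PCG
    p-distance is driven to ``target_p_nt`` by construction.
    """
    rng = np.random.default_rng(config.seed)
    truth = SyntheticTruth(pattern=config.pattern)

    ancestor = make_ancestor(config, rng)

    d = config.species_divergence
    if config.pattern == "gender_joining":
        # deep F/M split undershoots the pairwise target slightly; the
        # per-species top-up then drives p(F_s, M_s) to the target exactly
        e = _compose_p(d, d)
        deep = max(0.0, config.target_p_nt - 0.02)
        p0 = max(0.0, (deep - e) / (1.0 - (4.0 / 3.0) * e))
        m_root = ancestor.copy()
        _evolve_builder(rng, m_root, p0, config.target_omega, config.kappa,
                        ref=ancestor, noncoding_p=p0)
    else:
        m_root = None

    genomes: list[AnnotatedGenome] = []
    names = [f"Species{chr(ord('A') + i)}" for i in range(config.n_species)]
    for si, sp in enumerate(names):
        F = ancestor.copy()
        _evolve_builder(rng, F, d, config.target_omega, config.kappa,
                        ref=ancestor, noncoding_p=d)
        if config.pattern == "gender_joining":
            M = m_root.copy()
            _evolve_builder(rng, M, _compose_p(p0, d), config.target_omega,
                            config.kappa, ref=ancestor, noncoding_p=d)
            nc_top = 0.0
        else:
            M = F.copy()
            nc_top = config.target_p_nt
        # top up M against its own species F until the pairwise target holds
        _evolve_builder(rng, M, config.target_p_nt, config.target_omega,
                        config.kappa, ref=F, noncoding_p=nc_top)

        # F-orf between nad2 and trnM
        Fp = F.copy()
        i = Fp.index_of("trnM")
        Fp.segments[i:i] = [
            Segment(seq=_make_cds(rng, 3 * (config.f_orf_codons + 1),
                                  config.at_fraction),
                    name="F-orf", kind="ORFan", coding=True, emit=True, tag="F-orf"),
            Segment(seq=_random_seq(rng, 10, config.at_fraction)),
        ]
        Mp, meta = plant_features(M, config, rng)

        f_id, m_id = f"{sp}_F", f"{sp}_M"
        genomes.append(_finalize(Fp, f_id, sp, "F", rng, truth, config=config))
        genomes.append(_finalize(Mp, m_id, sp, "M", rng, truth, meta, config=config))
        truth.fm_pairs.append((f_id, m_id))

        if config.include_h and si == 0:
            H = F.copy()
            _evolve_builder(rng, H, 0.01, config.target_omega, config.kappa, ref=F)
            genomes.append(_finalize(H, f"{sp}_H", sp, "H", rng, truth, config=config))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for g in genomes:
            write_genbank(g, out / f"{g.id}.gb")
        labels = pd.DataFrame(
            [{"genome": g.id, "species": truth.species[g.id],
              "route": truth.routes[g.id]} for g in genomes])
        labels.to_csv(out / "labels.tsv", sep="\t", index=False)
        rows = []
        for gid, orfs in truth.planted_orfs.items():
            for o in orfs:
                rows.append({"genome": gid, **{k: o[k] for k in ("tag", "start", "end")}})
        pd.DataFrame(rows).to_csv(out / "planted_orfs.tsv", sep="\t", index=False)
    return genomes, truth
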