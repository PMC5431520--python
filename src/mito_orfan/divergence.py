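"""Sequence divergence and composition statistics.

Implements the counting statistics used to compare F- and M-transmitted
mitogenomes: nucleotide and amino-acid p-distance, the Nei–Gojobori
(1986) dN/dS estimator with Jukes–Cantor correction, relative
synonymous codon usage (RSCU), base composition and strand skews, and a
per-gene + concatenated F-vs-M divergence report.

Nei–Gojobori conventions used here (the standard 1986 treatment):

* Synonymous site fractions per codon come from enumerating the three
  possible single-nucleotide changes at each position; changes creating
  a stop codon are excluded from the fraction's denominator, so every
  codon still contributes exactly 3 sites split between S and N.
* Codon pairs differing at k positions are averaged over all k!
  mutational pathways; pathways passing through a stop codon are
  excluded (if every pathway is invalid the pair falls back to an
  unweighted average over all pathways and the result is flagged).
* Site totals are averaged over the two sequences; pS = Sd/S, pN = Nd/N;
  Jukes–Cantor correction d = -(3/4) ln(1 - (4/3) p), undefined for
  p >= 3/4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from .align import needleman_wunsch
from .genome import AnnotatedGenome
from .orfs import _codon_table, translate

__all__ = [
    "CodonAlignment",
    "DivergenceResult",
    "p_distance",
    "nei_gojobori",
    "rscu",
    "composition",
    "build_codon_alignment",
    "fm_divergence_report",
]


# p-distance -----------------------------------------------------------------


def p_distance(a: str, b: str, mode: str = "nt") -> float:
    """Proportion of differing sites among compared aligned sites.

    Columns containing a gap, N (nt) or X (aa) in either sequence are
    excluded from both numerator and denominator (pairwise deletion).
    """
    if len(a) != len(b):
        raise ValueError(f"aligned sequences differ in length ({len(a)} vs {len(b)})")
    skip = {"-", "N"} if mode == "nt" else {"-", "X"}
    compared = diffs = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in skip or y in skip:
            continue
        compared += 1
        if x != y:
            diffs += 1
    if compared == 0:
        return float("nan")
    return diffs / compared


# Nei–Gojobori ---------------------------------------------------------------


@dataclass
class CodonAlignment:
    """Pair of equal-length gapped coding sequences, gaps in whole codons."""

    gene: str
    a: str
    b: str

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError(f"{self.gene}: aligned lengths differ")
        if len(self.a) % 3:
            raise ValueError(f"{self.gene}: aligned length not divisible by 3")
        for s in (self.a, self.b):
            for i in range(0, len(s), 3):
                codon = s[i:i + 3]
                if "-" in codon and codon != "---":
                    raise ValueError(f"{self.gene}: gap not in whole-codon units at {i}")

    def codon_pairs(self) -> list[tuple[str, str]]:
        """Codon columns with no gap and no N in either sequence."""
        out = []
        for i in range(0, len(self.a), 3):
            ca, cb = self.a[i:i + 3].upper(), self.b[i:i + 3].upper()
            if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
                continue
            out.append((ca, cb))
        return out


@dataclass
class DivergenceResult:
    """Divergence statistics for one gene pair or a concatenation."""

    gene: str
    n_codons: int = 0
    p_nt: float = float("nan")
    p_aa: float = float("nan")
    S_sites: float = 0.0
    N_sites: float = 0.0
    Sd: float = 0.0
    Nd: float = 0.0
    pS: float = float("nan")
    pN: float = float("nan")
    dS: float | None = None
    dN: float | None = None
    omega: float | None = None
    flags: list[str] = field(default_factory=list)


def _syn_site_fractions(table: int) -> dict[str, float]:
    """Synonymous sites per sense codon (stop-mutation-excluded fractions)."""
    t = _codon_table(table)
    out: dict[str, float] = {}
    for codon, aa in t.forward_table.items():
        s = 0.0
        for pos in range(3):
            syn = valid = 0
            for nt in "ACGT":
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1:]
                if alt in t.stop_codons:
                    continue
                valid += 1
                if t.forward_table[alt] == aa:
                    syn += 1
            if valid:
                s += syn / valid
        out[codon] = s
    return out


_SYN_SITES_CACHE: dict[int, dict[str, float]] = {}


def _pathway_counts(ca: str, cb: str, table: int) -> tuple[float, float, bool]:
    """(Sd, Nd, fallback_used) for one codon pair, pathway-averaged."""
    t = _codon_table(table)
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0, False

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        cur = ca
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in t.stop_codons and not allow_stops:
                return None
            aa_cur = "*" if cur in t.stop_codons else t.forward_table[cur]
            aa_nxt = "*" if nxt in t.stop_codons else t.forward_table[nxt]
            if aa_cur == aa_nxt:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    results = [r for order in permutations(diff_pos) if (r := walk(order, False))]
    fallback = False
    if not results:
        fallback = True
        results = [walk(order, True) for order in permutations(diff_pos)]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd, fallback


def jukes_cantor(p: float) -> float | None:
    """JC-corrected distance; None when p >= 3/4 (undefined)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def nei_gojobori(
    aln: CodonAlignment, table: int = 5, correction: str = "jukes_cantor"
) -> DivergenceResult:
    """Nei–Gojobori dN/dS for a pairwise codon alignment."""
    if correction not in ("none", "jukes_cantor"):
        raise ValueError(f"unknown correction {correction!r}")
    if table not in _SYN_SITES_CACHE:
        _SYN_SITES_CACHE[table] = _syn_site_fractions(table)
    syn_sites = _SYN_SITES_CACHE[table]

    res = DivergenceResult(gene=aln.gene)
    pairs = aln.codon_pairs()
    res.n_codons = len(pairs)
    if not pairs:
        res.flags.append("no_comparable_codons")
        return res

    Sa = Sb = 0.0
    for ca, cb in pairs:
        if ca in syn_sites and cb in syn_sites:
            Sa += syn_sites[ca]
            Sb += syn_sites[cb]
        else:
            res.flags.append("stop_codon_in_alignment")
    res.S_sites = (Sa + Sb) / 2.0
    res.N_sites = 3.0 * len(pairs) - res.S_sites

    for ca, cb in pairs:
        sd, nd, fb = _pathway_counts(ca, cb, table)
        res.Sd += sd
        res.Nd += nd
        if fb:
            res.flags.append("all_pathways_through_stops")

    res.p_nt = p_distance(aln.a, aln.b, "nt")
    prot_a = "".join(translate(ca, table, allow_internal_stop=True) or "X" for ca, _ in pairs)
    prot_b = "".join(translate(cb, table, allow_internal_stop=True) or "X" for _, cb in pairs)
    res.p_aa = p_distance(prot_a, prot_b, "aa")

    res.pS = res.Sd / res.S_sites if res.S_sites > 0 else float("nan")
    res.pN = res.Nd / res.N_sites if res.N_sites > 0 else float("nan")
    if res.pS > 1:
        res.flags.append("pS_exceeds_1")

    if correction == "none":
        res.dS, res.dN = res.pS, res.pN
    else:
        res.dS = jukes_cantor(res.pS) if not math.isnan(res.pS) else None
        res.dN = jukes_cantor(res.pN) if not math.isnan(res.pN) else None
        if res.dS is None:
            res.flags.append("dS_undefined")
        if res.dN is None:
            res.flags.append("dN_undefined")

    if res.dS is None or res.dN is None or res.dS == 0:
        res.omega = None
        if res.dS == 0:
            res.flags.append("omega_undefined_dS_zero")
    else:
        res.omega = res.dN / res.dS
    return res


# RSCU and composition -------------------------------------------------------


def rscu(cds_set: list[str], table: int = 5) -> pd.DataFrame:
    """Relative synonymous codon usage over a set of coding sequences.

    RSCU(codon) = count * family_size / family_total, families grouped
    by amino acid under the given code; stop codons excluded.  A family
    never used gets RSCU 0 for all members and is flagged.
    """
    t = _codon_table(table)
    counts: dict[str, int] = {c: 0 for c in t.forward_table}
    for cds in cds_set:
        cds = cds.upper()
        if len(cds) % 3:
            raise ValueError("CDS length not divisible by 3")
        for i in range(0, len(cds), 3):
            codon = cds[i:i + 3]
            if codon in counts:
                counts[codon] += 1
    families: dict[str, list[str]] = {}
    for codon, aa in t.forward_table.items():
        families.setdefault(aa, []).append(codon)
    rows = []
    for aa in sorted(families):
        fam = sorted(families[aa])
        total = sum(counts[c] for c in fam)
        for codon in fam:
            value = counts[codon] * len(fam) / total if total else 0.0
            rows.append({"aa": aa, "codon": codon, "count": counts[codon],
                         "rscu": value, "unused_family": total == 0})
    return pd.DataFrame(rows)


def composition(seq: str) -> dict[str, float]:
    """Base fractions, AT%, AT-skew (A-T)/(A+T) and GC-skew (G-C)/(G+C).

    N is excluded from all counts; fractions sum to 1 over counted bases.
    """
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence has no ACGT bases")
    at = counts["A"] + counts["T"]
    gc = counts["G"] + counts["C"]
    return {
        "fA": counts["A"] / total,
        "fC": counts["C"] / total,
        "fG": counts["G"] / total,
        "fT": counts["T"] / total,
        "AT%": 100.0 * at / total,
        "AT_skew": (counts["A"] - counts["T"]) / at if at else float("nan"),
        "GC_skew": (counts["G"] - counts["C"]) / gc if gc else float("nan"),
    }


# F vs M report --------------------------------------------------------------


def build_codon_alignment(gene: str, nt_a: str, nt_b: str, table: int = 5) -> CodonAlignment:
    """Codon alignment of two coding sequences via protein alignment.

    Proteins are globally aligned (BLOSUM62, gap 11/1, free end gaps —
    so a 3'-extended M-type cox2 aligns as an overhang) and codons are
    threaded back through the protein gaps.
    """
    def prep(nt: str) -> str:
        nt = nt[: len(nt) - len(nt) % 3]
        prot = translate(nt, table, allow_internal_stop=True)
        return nt, prot

    nt_a, prot_a = prep(nt_a)
    nt_b, prot_b = prep(nt_b)
    # X from N-codons is fine for alignment scoring
    ga, gb, _ = needleman_wunsch(prot_a, prot_b, is_protein=True)

    def thread(gapped: str, nt: str) -> str:
        out, i = [], 0
        for aa in gapped:
            if aa == "-":
                out.append("---")
            else:
                out.append(nt[i:i + 3])
                i += 3
        return "".join(out)

    return CodonAlignment(gene=gene, a=thread(ga, nt_a), b=thread(gb, nt_b))


def fm_divergence_report(
    F: AnnotatedGenome,
    M: AnnotatedGenome,
    alignments: dict[str, CodonAlignment] | None = None,
    table: int = 5,
) -> pd.DataFrame:
    """Per-gene and concatenated F-vs-M divergence table.

    Orthologous PCGs are paired by name (missing orthologs skipped with
    a warning); the headline "overall" statistics are computed on the
    concatenation of the 13 PCG codon alignments, with a per-gene mean
    emitted alongside.  rRNA genes (rrnS/rrnL) get nucleotide
    p-distances only.
    """
    import logging
    log = logging.getLogger("mito_orfan")

    if alignments is None:
        alignments = {}
        for f in F.features:
            if f.kind != "PCG":
                continue
            if not M.has(f.name):
                log.warning("%s missing in %s; gene skipped", f.name, M.id)
                continue
            alignments[f.name] = build_codon_alignment(
                f.name, F.feature_seq(f), M.feature_seq(M.get(f.name)), table)

    rows = []
    results = []
    for gene, aln in alignments.items():
        r = nei_gojobori(aln, table)
        results.append(r)
        rows.append(_result_row(r))

    if results:
        concat = CodonAlignment(
            gene="concatenated",
            a="".join(alignments[g].a for g in alignments),
            b="".join(alignments[g].b for g in alignments),
        )
        rows.append(_result_row(nei_gojobori(concat, table)))
        omegas = [r.omega for r in results if r.omega is not None]
        rows.append({
            "gene": "gene_mean",
            "p_nt": float(np.nanmean([r.p_nt for r in results])),
            "p_aa": float(np.nanmean([r.p_aa for r in results])),
            "omega": float(np.mean(omegas)) if omegas else float("nan"),
        })

    for rname in ("rrnS", "rrnL"):
        if F.has(rname) and M.has(rname):
            a, b = F.feature_seq(F.get(rname)), M.feature_seq(M.get(rname))
            if len(a) != len(b):
                a, b, _ = needleman_wunsch(a, b, is_protein=False)
            rows.append({"gene": rname, "p_nt": p_distance(a, b, "nt")})
    return pd.DataFrame(rows)


def _result_row(r: DivergenceResult) -> dict:
    return {
        "gene": r.gene, "n_codons": r.n_codons, "p_nt": r.p_nt, "p_aa": r.p_aa,
        "S_sites": r.S_sites, "N_sites": r.N_sites, "Sd": r.Sd, "Nd": r.Nd,
        "pS": r.pS, "pN": r.pN,
        "dS": r.dS if r.dS is not None else float("nan"),
        "dN": r.dN if r.dN is not None else float("nan"),
        "omega": r.omega if r.omega is not None else float("nan"),
        "flags": ";".join(sorted(set(r.flags))),
    }
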