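"""Independent brute-force oracles used by the test suite.

Each oracle recomputes the quantity under test by direct enumeration,
deliberately sharing no code path with the package implementation.
"""

from __future__ import annotations

from itertools import combinations, permutations

from Bio.Data import CodonTable
from Bio.Seq import Seq

T5 = CodonTable.unambiguous_dna_by_id[5]
START5 = set(T5.start_codons)
STOP5 = set(T5.stop_codons)


def aa_of(codon: str) -> str:
    return "*" if codon in STOP5 else str(Seq(codon).translate(table=5))


# --- ORF scanning -----------------------------------------------------------


def brute_force_orfs(seq: str, min_codons: int = 10):
    """All (start, end, strand) ORF spans, forward coordinates.

    Direct enumeration: for every strand/position pair, walk codons to
    the first in-frame stop; keep start->stop runs with >= min_codons
    sense codons where the start is the first start codon after the
    previous in-frame stop (longest-per-stop).
    """
    out = set()
    n = len(seq)
    for strand in ("+", "-"):
        s = seq if strand == "+" else str(Seq(seq).reverse_complement())
        for frame in range(3):
            stops = [frame - 3] + [p for p in range(frame, n - 2, 3) if s[p:p + 3] in STOP5]
            for prev, stop in zip(stops, stops[1:]):
                starts = [p for p in range(prev + 3, stop, 3) if s[p:p + 3] in START5]
                if not starts:
                    continue
                a, b = starts[0], stop + 3
                if b - a >= (min_codons + 1) * 3:
                    if strand == "+":
                        out.add((a, b, "+"))
                    else:
                        out.add((n - b, n - a, "-"))
    return out


# --- Nei-Gojobori -----------------------------------------------------------


def ng_site_fractions(codon: str) -> float:
    """Synonymous sites of one sense codon (stop mutations excluded)."""
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if alt in STOP5:
                continue
            tot += 1
            syn += aa_of(alt) == aa_of(codon)
        if tot:
            s += syn / tot
    return s


def ng_pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) averaged over stop-free mutational pathways."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in permutations(diffs):
        cur, sd, nd, valid = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP5:
                valid = False
                break
            if aa_of(nxt) == aa_of(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if valid:
            paths.append((sd, nd))
    if not paths:  # fall back over all pathways, stop steps nonsynonymous
        for order in permutations(diffs):
            cur, sd, nd = c1, 0, 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if aa_of(nxt) == aa_of(cur):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


# --- Smith-Waterman ---------------------------------------------------------


def enumerate_local_score(a: str, b: str, score, open_: float = 11.0,
                          extend: float = 1.0) -> float:
    """Optimal local alignment score by exhaustive enumeration.

    Considers every monotone set of matched index pairs; internal gaps
    cost open + extend*(L-1); terminal gaps are free (local).
    """
    def gap(L: int) -> float:
        return 0.0 if L == 0 else open_ + extend * (L - 1)

    best = 0.0
    la, lb = len(a), len(b)
    for k in range(1, min(la, lb) + 1):
        for ia in combinations(range(la), k):
            for ib in combinations(range(lb), k):
                s = sum(score(a[i], b[j]) for i, j in zip(ia, ib))
                for t in range(k - 1):
                    s -= gap(ia[t + 1] - ia[t] - 1) + gap(ib[t + 1] - ib[t] - 1)
                if s > best:
                    best = s
    return best


# --- TDRL -------------------------------------------------------------------


def tdrl_reachable(n: int, circular: bool = False) -> set[tuple[int, ...]]:
    """All permutations of range(n) reachable from identity by one
    tandem duplication + random loss, by direct replay."""
    ident = tuple(range(n))
    out = {ident}
    starts = range(n) if circular else range(n)
    for i in starts:
        rot = ident[i:] + ident[:i] if circular else ident
        max_blk = n if circular else n - i
        for blk in range(1, max_blk + 1):
            if not circular:
                block, prefix, suffix = rot[i:i + blk], rot[:i], rot[i + blk:]
            else:
                block, prefix, suffix = rot[:blk], (), rot[blk:]
            for mask in range(2 ** blk):
                keep1 = tuple(g for t, g in enumerate(block) if mask >> t & 1)
                keep2 = tuple(g for t, g in enumerate(block) if not mask >> t & 1)
                res = prefix + keep1 + keep2 + suffix
                if circular:
                    res = min(res[k:] + res[:k] for k in range(n))
                out.add(res)
    return out


def canon_circ(p: tuple[int, ...]) -> tuple[int, ...]:
    return min(p[k:] + p[:k] for k in range(len(p)))


# --- trees ------------------------------------------------------------------


def all_unrooted_topologies(labels: list[str]):
    """Every unrooted binary topology as an edge list, by leaf insertion."""
    # edges are (u, v); internal nodes get negative ids
    def insert(edges, leaf, next_internal):
        out = []
        for idx, (u, v) in enumerate(edges):
            w = next_internal
            new = [e for i, e in enumerate(edges) if i != idx]
            new += [(u, w), (w, v), (w, leaf)]
            out.append(new)
        return out

    trees = [[(labels[0], labels[1]), (labels[1], labels[2])]] if len(labels) >= 3 else []
    # start from the unique 3-leaf star
    star = -1
    trees = [[(labels[0], star), (labels[1], star), (labels[2], star)]]
    nxt = -2
    for leaf in labels[3:]:
        trees = [t2 for t in trees for t2 in insert(t, leaf, nxt)]
        nxt -= 1
    return trees


def canon_split(side: set, labels: set) -> frozenset:
    """Canonical representative of a bipartition (size, then lexicographic)."""
    other = labels - set(side)
    a, b = tuple(sorted(side)), tuple(sorted(other))
    return frozenset(side) if (len(a), a) < (len(b), b) else frozenset(other)


def tree_splits(edges, labels: set[str]) -> set[frozenset]:
    """Nontrivial bipartitions of an edge-list tree, canonicalized."""
    import networkx as nx

    g = nx.Graph(edges)
    splits = set()
    for u, v in list(g.edges):
        g.remove_edge(u, v)
        side = {x for x in nx.node_connected_component(g, u) if x in labels}
        g.add_edge(u, v)
        if 2 <= len(side) <= len(labels) - 2:
            splits.add(canon_split(side, labels))
    return splits


def path_length_matrix(edges, lengths, tips: list[str]):
    import networkx as nx
    import numpy as np

    g = nx.Graph()
    for e, L in zip(edges, lengths):
        g.add_edge(*e, weight=L)
    n = len(tips)
    d = np.zeros((n, n))
    for i in range(n):
        dist = nx.single_source_dijkstra_path_length(g, tips[i])
        for j in range(n):
            d[i, j] = dist[tips[j]]
    return d
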