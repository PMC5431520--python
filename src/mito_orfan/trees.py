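"""Distance-based trees and transmission-pattern classification.

Under doubly uniparental inheritance with a single origin and no
role-reversal events, all M-transmitted mitogenomes should be
reciprocally monophyletic with respect to the F (and F-derived H)
genomes — the gender-joining pattern.  Recurrent masculinization
instead makes each species' F and M sequences cluster together — the
taxon-joining pattern.  This module builds neighbor-joining trees from
p-distance matrices and classifies the resulting unrooted topology.

Classification is purely topological:

* gender_joining — some edge bipartition separates all M tips from all
  F/H tips;
* taxon_joining — every species' tips form a cherry, operationalized as
  an edge bipartition separating exactly that species' tips from the
  rest (labelled as such in output, since the pattern has no formal
  definition beyond species-wise clustering);
* mixed — neither; the evidence names the violating species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .divergence import p_distance

logger = logging.getLogger("mito_orfan")

__all__ = [
    "DistanceMatrix",
    "LabelledTree",
    "distance_matrix",
    "neighbor_joining",
    "classify_pattern",
    "PatternCall",
]


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if (v < 0).any():
            raise ValueError("distance matrix has negative entries")
        object.__setattr__(self, "values", v)

    def to_phylip(self) -> str:
        lines = [str(len(self.labels))]
        for i, lab in enumerate(self.labels):
            lines.append(lab + "  " + "  ".join(f"{x:.6f}" for x in self.values[i]))
        return "\n".join(lines) + "\n"


@dataclass
class LabelledTree:
    """Unrooted tree whose tips carry (species, transmission route)."""

    tree: dendropy.Tree
    routes: dict[str, str]  # tip label -> F | M | H
    species: dict[str, str]  # tip label -> species

    @classmethod
    def from_newick(cls, newick: str, sep: str = "|") -> "LabelledTree":
        """Tip labels encode species and route as ``species|route``."""
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        routes, species = {}, {}
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label
            sp, route = label.rsplit(sep, 1)
            routes[label] = route
            species[label] = sp
        return cls(tree=tree, routes=routes, species=species)

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]


def distance_matrix(sequences: dict[str, str], mode: str = "p_nt") -> DistanceMatrix:
    """Pairwise distance matrix over an aligned sequence set.

    Modes: ``p_nt`` / ``p_aa`` (raw p-distances) or ``jc_nt``
    (Jukes–Cantor-corrected nucleotide distance).  For tree building at
    the deep F/M divergences typical of DUI comparisons, use ``jc_nt``:
    raw p-distances saturate, compress the deepest pairs and can distort
    neighbor joining; the JC transform restores additivity.  p >= 3/4 is
    clamped just below the JC pole.
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    if mode not in ("p_nt", "p_aa", "jc_nt"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = tuple(sequences)
    pmode = "aa" if mode == "p_aa" else "nt"
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance(sequences[labels[i]], sequences[labels[j]], pmode)
            if mode == "jc_nt":
                p = -0.75 * np.log(1.0 - (4.0 / 3.0) * min(p, 0.7499))
            d[i, j] = d[j, i] = p
    return DistanceMatrix(labels=labels, values=d)


def neighbor_joining(d: DistanceMatrix, routes: dict[str, str] | None = None,
                     species: dict[str, str] | None = None) -> LabelledTree:
    """Saitou–Nei neighbor joining with the Q-criterion.

    Recovers additive matrices exactly; negative branch lengths are
    clamped to zero with a warning.  Tip routes/species default to
    parsing labels as ``species|route``.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 tips")
    D = d.values.astype(float).copy()
    nodes = [f"__leaf{i}" for i in range(n)]
    newick = {nodes[i]: d.labels[i] for i in range(n)}
    active = list(range(n))
    clamped = False
    next_id = n
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(q), q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        a, b = active[i_], active[j_]
        dij = D[a, b]
        la = 0.5 * dij + (r[i_] - r[j_]) / (2 * (m - 2))
        lb = dij - la
        if la < 0 or lb < 0:
            clamped = True
            la, lb = max(la, 0.0), max(lb, 0.0)
        # new node u
        u = next_id
        next_id += 1
        du = 0.5 * (D[a, :] + D[b, :] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[u, : u] = du[: u]
        D[: u, u] = du[: u]
        newick[f"__n{u}"] = f"({newick[nodes[a]]}:{la:.10f},{newick[nodes[b]]}:{lb:.10f})"
        nodes.append(f"__n{u}")
        del newick[nodes[a]], newick[nodes[b]]
        active = [x for x in active if x not in (a, b)] + [u]
    # final three-way join
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    if min(la, lb, lc) < 0:
        clamped = True
        la, lb, lc = max(la, 0.0), max(lb, 0.0), max(lc, 0.0)
    if clamped:
        logger.warning("neighbor joining clamped negative branch lengths to 0")
    nw = (f"({newick[nodes[a]]}:{la:.10f},{newick[nodes[b]]}:{lb:.10f},"
          f"{newick[nodes[c]]}:{lc:.10f});")
    tree = dendropy.Tree.get(data=nw, schema="newick", preserve_underscores=True)
    labels = list(d.labels)
    if routes is None or species is None:
        routes, species = {}, {}
        for lab in labels:
            if "|" in lab:
                sp, route = lab.rsplit("|", 1)
            else:
                sp, route = lab, "F"
            routes[lab] = route
            species[lab] = sp
    return LabelledTree(tree=tree, routes=routes, species=species)


@dataclass(frozen=True)
class PatternCall:
    pattern: str  # gender_joining | taxon_joining | mixed
    evidence: str


def _bipartitions(tree: dendropy.Tree) -> list[frozenset]:
    """Leaf-label sets under each node: every edge bipartition appears."""
    out = []
    for node in tree.preorder_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        out.append(leaves)
    return out


def classify_pattern(tree: LabelledTree) -> PatternCall:
    """Classify an F/M(/H) tree as gender-joining, taxon-joining or mixed.

    H tips group with F (the H genome is F-derived).  The bipartition
    (gender-joining) test runs first; classification ignores branch
    lengths and rooting.
    """
    tips = tree.tip_labels
    if len(tips) < 4:
        raise ValueError("classification needs at least 4 tips")
    missing = [t for t in tips if t not in tree.routes]
    if missing:
        raise ValueError(f"tips without route labels: {missing}")
    m_tips = frozenset(t for t in tips if tree.routes[t] == "M")
    fh_tips = frozenset(t for t in tips if tree.routes[t] in ("F", "H"))
    all_tips = frozenset(tips)
    bips = _bipartitions(tree.tree)

    if m_tips and fh_tips:
        for side in bips:
            if side in (m_tips, fh_tips) or (all_tips - side) in (m_tips, fh_tips):
                return PatternCall(
                    pattern="gender_joining",
                    evidence="edge separates M tips {%s} from F/H tips"
                             % ",".join(sorted(m_tips)))

    by_species: dict[str, set[str]] = {}
    for t in tips:
        by_species.setdefault(tree.species[t], set()).add(t)
    violators = []
    for sp, group in by_species.items():
        if len(group) < 2:
            continue
        fs = frozenset(group)
        if not any(side == fs or (all_tips - side) == fs for side in bips):
            violators.append(sp)
    if not violators:
        return PatternCall(pattern="taxon_joining",
                           evidence="every species' F/M tips form a cherry")
    return PatternCall(pattern="mixed",
                       evidence="species without private clade: %s"
                                % ",".join(sorted(violators)))
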