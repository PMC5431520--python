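"""Data model and I/O for annotated circular mitochondrial genomes.

The unit of analysis is :class:`AnnotatedGenome`: a circular (or
linear-with-gaps) mtDNA sequence plus an ordered list of typed
:class:`GeneFeature` records drawn from the standard metazoan
mitochondrial vocabulary (13 protein-coding genes, 2 rRNAs, 22 tRNAs with
Leu/Ser disambiguation) extended with the lineage-specific ORFan genes of
doubly uniparental inheritance (DUI) bivalves (F-orf / M-orf / H-orf) and
pseudogene fragments.

Coordinates are 0-based half-open throughout; GenBank's 1-based inclusive
convention exists only at the I/O boundary.  A feature on a circular
genome may wrap the origin, in which case ``end > length`` and the
feature occupies ``[start, length) + [0, end - length)``.

Unassigned regions (URs) are the maximal intervals covered by no feature.
They are numbered consecutively from 1, with number 1 assigned to the UR
immediately upstream of *cox1* and numbering proceeding clockwise
(ascending coordinates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, CompoundLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("mito_orfan")

__all__ = [
    "PCG_NAMES",
    "RRNA_NAMES",
    "TRNA_NAMES",
    "ORFAN_NAMES",
    "GeneFeature",
    "AnnotatedGenome",
    "UnassignedRegion",
    "normalize_gene_name",
    "read_genbank",
    "write_genbank",
    "write_fasta",
    "extract_unassigned_regions",
    "features_table",
    "urs_table",
]

# Controlled vocabulary ------------------------------------------------------

PCG_NAMES = (
    "atp6", "atp8", "cox1", "cox2", "cox3", "cytb",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)
RRNA_NAMES = ("rrnS", "rrnL")
# trnL1 = Leu(CUN), trnL2 = Leu(UUR); trnS1 = Ser(AGN), trnS2 = Ser(UCN)
TRNA_NAMES = tuple(
    "trn" + x
    for x in ("A", "C", "D", "E", "F", "G", "H", "I", "K", "L1", "L2",
              "M", "N", "P", "Q", "R", "S1", "S2", "T", "V", "W", "Y")
)
ORFAN_NAMES = ("F-orf", "M-orf", "H-orf")

_KIND_BY_NAME: dict[str, str] = {}
_KIND_BY_NAME.update({n: "PCG" for n in PCG_NAMES})
_KIND_BY_NAME.update({n: "rRNA" for n in RRNA_NAMES})
_KIND_BY_NAME.update({n: "tRNA" for n in TRNA_NAMES})
_KIND_BY_NAME.update({n: "ORFan" for n in ORFAN_NAMES})

VALID_ROUTES = ("F", "M", "H", "nonDUI", "unknown")
VALID_KINDS = ("PCG", "rRNA", "tRNA", "ORFan", "pseudogene_fragment", "other")


def _load_synonyms() -> dict[str, str]:
    table: dict[str, str] = {}
    path = resources.files("mito_orfan").joinpath("data/gene_synonyms.tsv")
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        alias, canonical = line.split("\t")
        table[alias.strip().lower()] = canonical.strip()
    return table


_SYNONYMS: dict[str, str] | None = None


def normalize_gene_name(raw: str) -> tuple[str, str]:
    """Map a raw gene label onto the controlled vocabulary.

    Returns ``(canonical_name, kind)``; unrecognized labels come back
    unchanged with kind ``"other"``.  Pseudogene labels ``pseudo:<gene>``
    are normalized on the inner gene name.
    """
    global _SYNONYMS
    if _SYNONYMS is None:
        _SYNONYMS = _load_synonyms()
    raw = raw.strip()
    if raw.startswith("pseudo:"):
        inner, _ = normalize_gene_name(raw[len("pseudo:"):])
        return f"pseudo:{inner}", "pseudogene_fragment"
    key = raw.lower().replace(" ", "")
    if key in _SYNONYMS:
        name = _SYNONYMS[key]
        return name, _KIND_BY_NAME.get(name, "other")
    if raw in _KIND_BY_NAME:
        return raw, _KIND_BY_NAME[raw]
    return raw, "other"


# Domain types ---------------------------------------------------------------


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on a mitogenome, 0-based half-open coordinates.

    ``end > length`` of the parent genome means the feature wraps the
    circular origin.  ``copy_index`` disambiguates duplicated genes
    (e.g. a second tRNA-Glu).
    """

    name: str
    kind: str
    start: int
    end: int
    strand: str = "+"
    codon_table: int = 5
    copy_index: int = 1
    incomplete_stop: bool = False

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(
                f"{self.name}: end ({self.end}) must exceed start ({self.start}); "
                "wrapping features use end > genome length"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.name, self.start, self.strand)

    @property
    def token(self) -> str:
        """Token used in gene-order permutations (copy-indexed)."""
        return self.name if self.copy_index == 1 else f"{self.name}.{self.copy_index}"


@dataclass
class AnnotatedGenome:
    """Circular mtDNA sequence plus its typed gene features."""

    id: str
    organism: str
    route: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    topology: str = "circular"

    def __post_init__(self) -> None:
        if self.route not in VALID_ROUTES:
            raise ValueError(f"route must be one of {VALID_ROUTES}, got {self.route!r}")
        if self.topology not in ("circular", "linear_with_gaps"):
            raise ValueError(f"bad topology {self.topology!r}")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence contains non-ACGTN symbols: {sorted(bad)}")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        self.validate()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for f in self.features:
            if not (0 <= f.start < self.length):
                raise ValueError(f"{f.name}: start {f.start} outside [0, {self.length})")
            if f.end > self.length:
                if self.topology != "circular":
                    raise ValueError(f"{f.name}: wrapping feature on non-circular genome")
                if f.end > f.start + self.length:
                    raise ValueError(f"{f.name}: wraps more than once")
            if f.key in seen:
                raise ValueError(f"duplicate feature key {f.key}; assign copy_index")
            seen.add(f.key)

    def feature_seq(self, f: GeneFeature) -> str:
        """Feature nucleotide sequence, reverse-complemented for '-' strand."""
        if f.end <= self.length:
            s = self.sequence[f.start:f.end]
        else:
            s = self.sequence[f.start:] + self.sequence[: f.end - self.length]
        if f.strand == "-":
            s = str(Seq(s).reverse_complement())
        return s

    def get(self, name: str, copy_index: int = 1) -> GeneFeature:
        for f in self.features:
            if f.name == name and f.copy_index == copy_index:
                return f
        raise KeyError(f"{name} (copy {copy_index}) not annotated on {self.id}")

    def has(self, name: str) -> bool:
        return any(f.name == name for f in self.features)


@dataclass(frozen=True)
class UnassignedRegion:
    """Maximal feature-free interval of a genome, numbered from 1.

    Index 1 is the UR immediately upstream of cox1; numbering proceeds
    in ascending-coordinate (clockwise) direction.  ``end > genome
    length`` marks the single allowed origin-wrapping UR.
    """

    genome_id: str
    index: int
    start: int
    end: int
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start


# GenBank / FASTA I/O --------------------------------------------------------

_KIND_TO_GB = {
    "PCG": "CDS",
    "ORFan": "CDS",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "pseudogene_fragment": "misc_feature",
    "other": "misc_feature",
}
_GB_FEATURE_TYPES = ("CDS", "rRNA", "tRNA", "misc_feature")


def _location_to_interval(loc, length: int) -> tuple[int, int, str]:
    strand = "-" if loc.strand == -1 else "+"
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        # origin-spanning join(X..length, 1..Y)
        if len(parts) == 2 and int(parts[-1].end) == length and int(parts[0].start) == 0:
            return int(parts[1].start), length + int(parts[0].end), strand
        raise ValueError(f"unsupported compound location {loc}")
    return int(loc.start), int(loc.end), strand


def _interval_to_location(f: GeneFeature, length: int) -> FeatureLocation | CompoundLocation:
    strand = -1 if f.strand == "-" else 1
    if f.end <= length:
        return FeatureLocation(f.start, f.end, strand=strand)
    first = FeatureLocation(f.start, length, strand=strand)
    second = FeatureLocation(0, f.end - length, strand=strand)
    parts = [first, second] if strand == 1 else [second, first]
    return CompoundLocation(parts)


def read_genbank(path: str | Path) -> AnnotatedGenome:
    """Parse a GenBank flat file into an :class:`AnnotatedGenome`.

    Feature labels are mapped into the controlled vocabulary via the
    shipped synonym table; unknown labels are kept with kind ``other``
    (with a warning).  Missing sequence is fatal.
    """
    record = SeqIO.read(str(path), "genbank")
    seq = str(record.seq)
    if not seq or set(seq) == {"N"} and len(seq) == 0:
        raise ValueError(f"{path}: GenBank record has no ORIGIN sequence")
    topology = record.annotations.get("topology", "circular")
    topo = "circular" if topology == "circular" else "linear_with_gaps"
    route = record.annotations.get("mito_orfan_route", "unknown")
    organism = record.annotations.get("organism", record.description or record.id)

    feats: list[GeneFeature] = []
    counts: dict[tuple[str, str], int] = {}
    for gbf in record.features:
        if gbf.type not in _GB_FEATURE_TYPES:
            continue
        quals = gbf.qualifiers
        raw = (quals.get("gene") or quals.get("product") or quals.get("note") or [None])[0]
        if raw is None:
            continue
        try:
            start, end, strand = _location_to_interval(gbf.location, len(seq))
        except ValueError as exc:
            raise ValueError(f"{path}: unparseable location for {raw!r}: {exc}") from exc
        name, kind = normalize_gene_name(raw)
        if kind == "other":
            logger.warning("%s: unknown gene label %r kept with kind 'other'", path, raw)
        if "route" in quals and quals["route"][0] in VALID_ROUTES:
            route = quals["route"][0]
        table = int(quals.get("transl_table", [5])[0])
        key = (name, strand)
        counts[key] = counts.get(key, 0) + 1
        feats.append(
            GeneFeature(
                name=name, kind=kind, start=start, end=end, strand=strand,
                codon_table=table, copy_index=counts[key],
                incomplete_stop="transl_except" in quals,
            )
        )
    # copy indices must disambiguate (name, start, strand); recount per name
    by_name: dict[str, int] = {}
    fixed: list[GeneFeature] = []
    for f in sorted(feats, key=lambda f: f.start):
        by_name[f.name] = by_name.get(f.name, 0) + 1
        fixed.append(replace(f, copy_index=by_name[f.name]))
    return AnnotatedGenome(
        id=record.id or record.name, organism=organism, route=route,
        sequence=seq, features=fixed, topology=topo,
    )


def write_genbank(genome: AnnotatedGenome, path: str | Path) -> None:
    """Write a standard-conformant GenBank flat file (1-based inclusive)."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id.split(".")[0][:16],
        description=f"{genome.organism} mitochondrion ({genome.route})",
    )
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if genome.topology == "circular" else "linear"
    record.annotations["organism"] = genome.organism
    record.annotations["date"] = "01-JAN-2016"  # fixed for byte-identical output
    record.annotations["mito_orfan_route"] = genome.route
    if not genome.features:
        logger.warning("%s: writing sequence-only record (no features)", genome.id)
    for f in genome.features:
        quals: dict[str, list] = {"gene": [f.name]}
        if f.kind in ("PCG", "ORFan"):
            quals["transl_table"] = [str(f.codon_table)]
        if f.copy_index > 1:
            quals["note"] = [f"copy {f.copy_index}"]
        quals["route"] = [genome.route]
        record.features.append(
            SeqFeature(_interval_to_location(f, genome.length), type=_KIND_TO_GB[f.kind],
                       qualifiers=quals)
        )
    SeqIO.write([record], str(path), "genbank")


def write_fasta(obj, path: str | Path) -> None:
    """Write a genome or ``{id: sequence}`` mapping as FASTA."""
    records = []
    if isinstance(obj, AnnotatedGenome):
        records.append(SeqRecord(Seq(obj.sequence), id=obj.id, description=obj.organism))
    else:
        for name, seq in dict(obj).items():
            records.append(SeqRecord(Seq(str(seq)), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


# Unassigned regions ---------------------------------------------------------


def extract_unassigned_regions(
    genome: AnnotatedGenome, anchor: str = "cox1"
) -> list[UnassignedRegion]:
    """Maximal feature-free intervals, numbered clockwise from the anchor.

    Index 1 goes to the UR immediately upstream of the anchor gene
    (default cox1): the UR whose end abuts — or, failing that, lies
    nearest below — the anchor's start on the circle.
    """
    L = genome.length
    covered = np.zeros(L, dtype=bool)
    for f in genome.features:
        if f.end <= L:
            covered[f.start:f.end] = True
        else:
            covered[f.start:] = True
            covered[: f.end - L] = True
    if covered.all():
        return []

    # uncovered runs on the linear sequence
    uncov = ~covered
    edges = np.flatnonzero(np.diff(np.concatenate(([0], uncov.view(np.int8), [0]))))
    runs = [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]
    # merge a run touching the end with a run starting at 0 (circular wrap)
    if genome.topology == "circular" and len(runs) > 1 and runs[0][0] == 0 and runs[-1][1] == L:
        first, last = runs[0], runs[-1]
        runs = runs[1:-1] + [(last[0], L + first[1])]
    runs.sort()

    if not genome.has(anchor):
        raise ValueError(
            f"{genome.id}: no {anchor!r} feature to anchor UR numbering; "
            "supply anchor= explicitly"
        )
    a_start = genome.get(anchor).start
    # UR immediately upstream: end abuts anchor start (mod L); otherwise the
    # nearest UR ending upstream of the anchor on the circle.
    def upstream_gap(run: tuple[int, int]) -> int:
        return (a_start - run[1]) % L

    first_idx = min(range(len(runs)), key=lambda i: upstream_gap(runs[i]))
    ordered = runs[first_idx:] + runs[:first_idx]

    out = []
    for i, (s, e) in enumerate(ordered, start=1):
        seq = genome.sequence[s:e] if e <= L else genome.sequence[s:] + genome.sequence[: e - L]
        out.append(UnassignedRegion(genome_id=genome.id, index=i, start=s, end=e, sequence=seq))
    return out


# Tabular dumps --------------------------------------------------------------


def features_table(genome: AnnotatedGenome) -> pd.DataFrame:
    rows = [
        {"genome": genome.id, "name": f.name, "kind": f.kind, "start": f.start,
         "end": f.end, "strand": f.strand, "length": f.length, "copy_index": f.copy_index}
        for f in genome.features
    ]
    return pd.DataFrame(rows)


def urs_table(urs: Sequence[UnassignedRegion]) -> pd.DataFrame:
    rows = [
        {"genome": u.genome_id, "index": u.index, "start": u.start, "end": u.end,
         "length": u.length}
        for u in urs
    ]
    return pd.DataFrame(rows)
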