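"""End-to-end orchestration of the comparative mitogenomics analysis.

Stage order: annotation check -> unassigned regions -> ORF census ->
homology screen -> F/M divergence -> gene order / TDRL / tandem
repeats -> transmission-pattern classification.  Inputs are GenBank
files or a simulated study; outputs are plain TSV tables plus a YAML
run manifest, so reruns with the same config and seed are
byte-identical and diffable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .divergence import fm_divergence_report
from .gene_order import (breakpoint_distance, find_tandem_repeats, gene_order,
                         tdrl_feasible)
from .genome import (AnnotatedGenome, extract_unassigned_regions, features_table,
                     read_genbank, urs_table)
from .orfs import census, default_ladder, genome_orfs, screen_ladder
from .simulate import SimConfig, simulate_study
from .trees import classify_pattern, distance_matrix, neighbor_joining

logger = logging.getLogger("mito_orfan")

__all__ = ["RunConfig", "run_all", "pcg_concat_alignment"]


@dataclass
class RunConfig:
    inputs: list[str] = field(default_factory=list)  # GenBank paths
    simulate: SimConfig | None = None  # used when no inputs given
    out_dir: str = "mito_orfan_out"
    min_codons: int = 10
    codon_table: int = 5
    screen_threshold: float = 50.0
    mask_k: int = 3
    repeat_min_period: int = 50
    repeat_min_identity: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if not self.inputs and self.simulate is None:
            raise ValueError("RunConfig needs input paths or a simulate config")
        if self.min_codons < 1:
            raise ValueError("min_codons must be positive")


def pcg_concat_alignment(genomes: list[AnnotatedGenome]) -> dict[str, str]:
    """Concatenated PCG pseudo-alignment across genomes.

    Genes present in every genome are truncated to their shortest copy
    (a 3'-extended M-cox2 loses only its overhang) and concatenated.
    Valid for genomes without indels in genes; accession data should go
    through explicit codon alignments instead.
    """
    shared = None
    for g in genomes:
        names = {f.name for f in g.features if f.kind == "PCG"}
        shared = names if shared is None else shared & names
    if not shared:
        raise ValueError("no shared protein-coding genes")
    out = {g.id: [] for g in genomes}
    for name in sorted(shared):
        seqs = {g.id: g.feature_seq(g.get(name)) for g in genomes}
        n = min(len(s) for s in seqs.values())
        for gid, s in seqs.items():
            out[gid].append(s[:n])
    return {gid: "".join(parts) for gid, parts in out.items()}


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the report bundle and writes TSV + manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reports: dict = {}

    truth = None
    if config.inputs:
        genomes = [read_genbank(p) for p in config.inputs]
    else:
        genomes, truth = simulate_study(config.simulate, out_dir=out / "genomes")
        reports["truth"] = truth

    # summary + URs
    summaries = []
    all_feats, all_urs = [], []
    for g in genomes:
        urs = extract_unassigned_regions(g)
        orfs = genome_orfs(g, min_codons=config.min_codons, table=config.codon_table)
        summaries.append({
            "genome": g.id, "organism": g.organism, "route": g.route,
            "length": g.length, "n_features": len(g.features),
            "n_pcg": sum(f.kind == "PCG" for f in g.features),
            "n_urs": len(urs), "n_orfs": len(orfs),
        })
        all_feats.append(features_table(g))
        all_urs.append(urs_table(urs))
    reports["summary"] = pd.DataFrame(summaries)
    reports["features"] = pd.concat(all_feats, ignore_index=True)
    reports["urs"] = pd.concat(all_urs, ignore_index=True)
    reports["census"] = census(genomes, min_codons=config.min_codons,
                               table=config.codon_table)

    # homology screen
    orfs = [o for g in genomes
            for o in genome_orfs(g, min_codons=config.min_codons,
                                 table=config.codon_table)]
    ladder = default_ladder(genomes, orfs)
    reports["screen"] = screen_ladder(orfs, ladder, threshold=config.screen_threshold)

    # F/M divergence per species
    by_species: dict[str, dict[str, AnnotatedGenome]] = {}
    for g in genomes:
        by_species.setdefault(g.organism, {})[g.route] = g
    div_tables = []
    for sp, pair in sorted(by_species.items()):
        if "F" in pair and "M" in pair:
            t = fm_divergence_report(pair["F"], pair["M"], table=config.codon_table)
            t.insert(0, "species", sp)
            div_tables.append(t)
    if div_tables:
        reports["divergence"] = pd.concat(div_tables, ignore_index=True)

    # gene order / TDRL / repeats
    orders = {g.id: gene_order(g) for g in genomes}
    bp_rows, tdrl_rows = [], []
    ids = [g.id for g in genomes]
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            shared = set(orders[a].names) & set(orders[b].names)
            ra, rb = orders[a].restrict(shared), orders[b].restrict(shared)
            bp_rows.append({"a": a, "b": b,
                            "breakpoint_distance": breakpoint_distance(ra, rb)})
    for sp, pair in sorted(by_species.items()):
        if "F" in pair and "M" in pair:
            fo, mo = orders[pair["F"].id], orders[pair["M"].id]
            shared = set(fo.names) & set(mo.names)
            ok, witness, reason = tdrl_feasible(fo.restrict(shared), mo.restrict(shared))
            tdrl_rows.append({"species": sp, "feasible": ok, "reason": reason,
                              "block": ",".join(witness.block) if witness else ""})
    reports["breakpoints"] = pd.DataFrame(bp_rows)
    reports["tdrl"] = pd.DataFrame(tdrl_rows)
    rep_rows = []
    for g in genomes:
        for r in find_tandem_repeats(g.sequence, min_period=config.repeat_min_period,
                                     min_identity=config.repeat_min_identity):
            rep_rows.append({"genome": g.id, "start": r.start, "end": r.end,
                             "period": r.period, "copies": r.copy_number,
                             "identity": round(r.mean_identity, 4)})
    reports["repeats"] = pd.DataFrame(
        rep_rows, columns=["genome", "start", "end", "period", "copies", "identity"])

    # transmission pattern
    routes = {g.id: g.route for g in genomes}
    species = {g.id: g.organism for g in genomes}
    classifiable = [g for g in genomes if g.route in ("F", "M", "H")]
    if len(classifiable) >= 4 and len({g.organism for g in classifiable}) >= 2:
        aln = pcg_concat_alignment(classifiable)
        dm = distance_matrix(aln, mode="jc_nt")
        tree = neighbor_joining(dm, routes=routes, species=species)
        call = classify_pattern(tree)
        reports["pattern"] = pd.DataFrame(
            [{"pattern": call.pattern, "evidence": call.evidence}])
        (out / "tree.nwk").write_text(
            tree.tree.as_string(schema="newick").strip() + "\n")

    for name, table in reports.items():
        if isinstance(table, pd.DataFrame):
            table.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    manifest = {
        "tool": "mito-orfan",
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items() if k != "simulate"},
        "simulate": asdict(config.simulate) if config.simulate else None,
        "genomes": [g.id for g in genomes],
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return reports
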