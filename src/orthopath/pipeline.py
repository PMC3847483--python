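"""End-to-end orchestration: align → annotate → score → assemble →
validate → integrate → export, with a reproducible run manifest.

The CLI is a thin wrapper over this module; every stage is also usable
directly from Python.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import __version__
from .annotate import AnnotationCandidate, FilterConfig, assign_functions
from .formats import (
    read_expression_tsv,
    read_fasta,
    read_pathway_template,
    write_pathway_graph,
)
from .omics import attach_overlay, fold_change_filter, map_probes
from .pathway import Pathway, build_pathway, pathway_stats, validate_against_known
from .records import index_by_id
from .score import (
    AnnotatedProtein,
    ScoreConfig,
    annotations_to_frame,
    plot_ms_cs,
    score_table,
    write_score_table,
)

log = logging.getLogger("orthopath")


@dataclass(frozen=True)
class RunConfig:
    """All inputs and thresholds for one reconstruction run."""

    query: Path
    templates: Mapping[str, Path]  # species -> proteome FASTA
    pathway_template: Path
    outdir: Path
    known_genes: Path | None = None
    gene_nucleotides: Path | None = None
    probes: Path | None = None
    expression: Path | None = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    scores: ScoreConfig = field(default_factory=ScoreConfig)
    validate_evalue: float = 1e-10
    validate_pident: float = 90.0
    probe_evalue: float = 1e-10
    probe_pident: float = 95.0
    fold: float = 2.0
    graph_format: str = "graphml"
    make_plot: bool = True

    def check(self) -> None:
        required = [self.query, self.pathway_template, *self.templates.values()]
        optional = [self.known_genes, self.gene_nucleotides, self.probes, self.expression]
        for p in required + [p for p in optional if p is not None]:
            if not Path(p).is_file():
                raise FileNotFoundError(f"input file not found: {p}")

    @classmethod
    def from_scenario_dir(cls, scenario: str | Path, outdir: str | Path, **overrides) -> "RunConfig":
        """Point the run at a generated scenario's standard layout."""
        scenario = Path(scenario)
        templates = {
            p.stem: p for p in sorted((scenario / "templates").glob("*.faa"))
        }
        defaults = dict(
            query=scenario / "query.faa",
            templates=templates,
            pathway_template=scenario / "pathway_template.json",
            outdir=Path(outdir),
            known_genes=_optional(scenario / "known_genes.faa"),
            gene_nucleotides=_optional(scenario / "genes.fna"),
            probes=_optional(scenario / "probes.fna"),
            expression=_optional(scenario / "expression.tsv"),
        )
        defaults.update(overrides)
        return cls(**defaults)


def _optional(path: Path) -> Path | None:
    return path if path.is_file() else None


@dataclass
class RunResult:
    pathway: Pathway
    annotations: list[AnnotatedProtein]
    candidates: list[AnnotationCandidate]
    outputs: dict[str, Path]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_reconstruct(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write every artifact to outdir."""
    config.check()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    log.info("stage align/annotate: reading inputs")
    query = index_by_id(read_fasta(config.query, "protein", species="query"))
    proteomes = {
        sp: index_by_id(read_fasta(path, "protein", species=sp))
        for sp, path in config.templates.items()
    }
    template = read_pathway_template(config.pathway_template)

    candidates = assign_functions(template, proteomes, query, config.filters)
    log.info("stage annotate: %d candidates from %d query proteins",
             len(candidates), len({c.query_id for c in candidates}))
    cand_path = outdir / "candidates.json"
    with open(cand_path, "w") as fh:
        json.dump([c.to_dict() for c in candidates], fh, indent=1, sort_keys=True)
        fh.write("\n")
    outputs["candidates"] = cand_path

    annotated, table = score_table(candidates, config.scores)
    log.info("stage score: regions %s", table["region"].value_counts().to_dict())

    pathway = build_pathway(template, annotated)
    stats = pathway_stats(pathway)
    log.info("stage assemble: %d reactions, %d gaps", stats.n_reactions, stats.n_gaps)
    stats.per_sub_pathway.to_csv(outdir / "stats_sub_pathway.tsv", sep="\t", index=False)
    stats.per_species.to_csv(outdir / "stats_species.tsv", sep="\t", index=False)
    outputs["stats_sub_pathway"] = outdir / "stats_sub_pathway.tsv"
    outputs["stats_species"] = outdir / "stats_species.tsv"

    if config.known_genes is not None:
        known = read_fasta(config.known_genes, "protein", species="known")
        report = validate_against_known(
            annotated, known, query,
            max_evalue=config.validate_evalue, min_pident=config.validate_pident,
        )
        log.info(
            "stage validate: %d/%d known genes matched (%d proteins), B∪C fraction %.3f",
            report.n_matched_genes, report.n_known, report.n_matched_proteins,
            report.fraction_validated_in_bc,
        )
        report.matched_pairs.to_csv(outdir / "validation_report.tsv", sep="\t", index=False)
        with open(outdir / "validation_summary.json", "w") as fh:
            summary = report.to_dict()
            summary.pop("matched_pairs")
            json.dump(summary, fh, indent=1)
            fh.write("\n")
        outputs["validation_report"] = outdir / "validation_report.tsv"

    # the table reflects post-validation flags
    table = annotations_to_frame(annotated)
    write_score_table(table, outdir / "score_table.tsv")
    outputs["score_table"] = outdir / "score_table.tsv"
    if config.make_plot:
        plot_ms_cs(table, outdir / "ms_cs_plot.png", config.scores)
        outputs["ms_cs_plot"] = outdir / "ms_cs_plot.png"

    if config.gene_nucleotides is not None and config.probes is not None and config.expression is not None:
        genes = read_fasta(config.gene_nucleotides, "nucleotide", species="query")
        probes = read_fasta(config.probes, "nucleotide", species="array")
        expr = read_expression_tsv(config.expression)
        mapping = map_probes(
            genes, probes, max_evalue=config.probe_evalue, min_pident=config.probe_pident
        )
        overlay = fold_change_filter(expr, mapping, fold=config.fold)
        attach_overlay(pathway, overlay)
        log.info(
            "stage integrate: %d genes mapped, %d passed the %.1f-fold filter",
            len(mapping), len(overlay.genes), config.fold,
        )
        overlay.to_frame().to_csv(outdir / "overlay.tsv", sep="\t", index=False)
        outputs["overlay"] = outdir / "overlay.tsv"

    graph_path = outdir / f"pathway.{config.graph_format}"
    write_pathway_graph(pathway, graph_path, fmt=config.graph_format)
    outputs["graph"] = graph_path
    with open(outdir / "pathway.json", "w") as fh:
        json.dump(pathway.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    outputs["pathway"] = outdir / "pathway.json"

    run_manifest = {
        "orthopath_version": __version__,
        "thresholds": {
            "max_evalue": config.filters.max_evalue,
            "min_pident": config.filters.min_pident,
            "min_qcov": config.filters.min_qcov,
            "n_templates": config.scores.n_templates,
            "region_ms_threshold": config.scores.region_ms_threshold,
            "region_cs_threshold": config.scores.region_cs_threshold,
            "validate_evalue": config.validate_evalue,
            "validate_pident": config.validate_pident,
            "probe_evalue": config.probe_evalue,
            "probe_pident": config.probe_pident,
            "fold": config.fold,
        },
        "inputs": {
            str(p): _sha256(Path(p))
            for p in [
                config.query, config.pathway_template, *config.templates.values(),
                *(x for x in (config.known_genes, config.gene_nucleotides,
                              config.probes, config.expression) if x is not None),
            ]
        },
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    outputs["run_manifest"] = outdir / "run_manifest.json"

    return RunResult(pathway=pathway, annotations=annotated, candidates=candidates, outputs=outputs)
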