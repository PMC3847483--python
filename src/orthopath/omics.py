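"""Transcriptome overlay: probe-to-gene mapping and fold-change filtering.

Microarray probes are mapped to annotated gene transcripts by local
nucleotide alignment (probe as query; inclusive E-value and identity
thresholds).  Gene-level expression per condition is the arithmetic mean
over the gene's mapped probes.  Only genes whose max/min condition ratio
reaches the fold threshold (default two-fold, the minimum clamped at a
small floor to avoid division by zero) enter the overlay attached to the
pathway graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .align import ScoringScheme, local_align
from .pathway import Pathway
from .records import SequenceRecord


@dataclass(frozen=True)
class GeneExpression:
    gene_id: str
    levels: tuple[float, ...]  # ordered by overlay.conditions
    probes: tuple[str, ...]
    fold_ratio: float
    passed_filter: bool

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "levels": list(self.levels),
            "probes": list(self.probes),
            "fold_ratio": self.fold_ratio,
            "passed_filter": self.passed_filter,
        }


@dataclass
class ExpressionOverlay:
    """Per-gene condition-expression vectors that passed the fold filter."""

    conditions: tuple[str, ...]
    genes: dict[str, GeneExpression]
    excluded: dict[str, GeneExpression] = field(default_factory=dict)

    def get(self, gene_id: str) -> GeneExpression | None:
        return self.genes.get(gene_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in sorted(self.genes.values(), key=lambda g: g.gene_id):
            rows.append(
                {
                    "gene_id": g.gene_id,
                    **{c: v for c, v in zip(self.conditions, g.levels)},
                    "n_probes": len(g.probes),
                    "probes": ";".join(g.probes),
                    "fold_ratio": g.fold_ratio,
                }
            )
        cols = ["gene_id", *self.conditions, "n_probes", "probes", "fold_ratio"]
        return pd.DataFrame(rows, columns=cols)

    def to_dict(self) -> dict:
        return {
            "conditions": list(self.conditions),
            "genes": {k: v.to_dict() for k, v in self.genes.items()},
            "excluded": {k: v.to_dict() for k, v in self.excluded.items()},
        }


def map_probes(
    genes: Sequence[SequenceRecord],
    probes: Sequence[SequenceRecord],
    scheme: ScoringScheme | None = None,
    max_evalue: float = 1e-10,
    min_pident: float = 95.0,
) -> dict[str, list[str]]:
    """Map probes to the genes they represent.

    Probe p represents gene g iff the best local alignment of p (query)
    against g satisfies E-value <= max_evalue and identity >= min_pident
    (inclusive).  A probe may represent several genes.  Keys are gene ids
    under the 12-digit gene/transcript convention where applicable.
    """
    for rec in (*genes, *probes):
        if rec.alphabet != "nucleotide":
            raise ValueError(f"map_probes requires nucleotide records, got {rec.id!r}")
    scheme = scheme or ScoringScheme.nucleotide_default()
    db_size = sum(len(g) for g in genes)
    mapping: dict[str, list[str]] = {}
    for gene in genes:
        matched = []
        for probe in probes:
            hit = local_align(probe, gene, scheme, database_residues=db_size)
            if hit is None:
                continue
            if hit.evalue <= max_evalue and hit.pident >= min_pident:
                matched.append(probe.id)
        if matched:
            mapping[gene.gene_id] = sorted(matched)
    return mapping


def fold_change_filter(
    table: pd.DataFrame,
    mapping: Mapping[str, Sequence[str]],
    fold: float = 2.0,
    floor: float = 1.0,
) -> ExpressionOverlay:
    """Aggregate probe expression per gene and apply the fold-change filter.

    Gene expression per condition is the arithmetic mean over its mapped
    probes; a gene passes iff max(levels)/max(min(levels), floor) >= fold.
    """
    if not len(mapping):
        raise ValueError("probe-to-gene mapping is empty")
    conditions = tuple(table.columns)
    passing: dict[str, GeneExpression] = {}
    excluded: dict[str, GeneExpression] = {}
    for gene_id in sorted(mapping):
        probe_ids = [p for p in mapping[gene_id] if p in table.index]
        if not probe_ids:
            warnings.warn(f"gene {gene_id!r}: no mapped probe has expression data; excluded")
            continue
        levels = tuple(float(v) for v in table.loc[sorted(probe_ids)].mean(axis=0))
        ratio = max(levels) / max(min(levels), floor)
        passed = ratio >= fold
        expr = GeneExpression(
            gene_id=gene_id, levels=levels, probes=tuple(sorted(probe_ids)),
            fold_ratio=ratio, passed_filter=passed,
        )
        (passing if passed else excluded)[gene_id] = expr
    return ExpressionOverlay(conditions=conditions, genes=passing, excluded=excluded)


def attach_overlay(pathway: Pathway, overlay: ExpressionOverlay) -> Pathway:
    """Attach the overlay to the pathway for graph export.

    Reaction nodes gain, per assigned protein whose gene passed the fold
    filter, the ordered condition-expression vector (see
    formats.build_pathway_graph).
    """
    pathway.overlay = overlay
    return pathway
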