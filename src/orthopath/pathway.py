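"""Pathway assembly: attach annotated proteins to template reactions by
EC number, detect metabolic gaps, and report reconstruction statistics.

A metabolic gap is a template reaction to which no query protein could be
annotated.  Known-gene validation aligns an externally curated protein
set against the annotated proteins (E-value and identity thresholds, both
inclusive) and reports how the validated annotations distribute over the
MS–CS confidence regions.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import ScoringScheme, local_align
from .records import PathwayTemplate, SequenceRecord, index_by_id
from .score import AnnotatedProtein


@dataclass
class Pathway:
    """Template reactions with attached annotated proteins and gap flags."""

    template: PathwayTemplate
    assignments: dict[str, list[AnnotatedProtein]]
    unplaced: list[AnnotatedProtein] = field(default_factory=list)
    overlay: object | None = None  # ExpressionOverlay, set by attach_overlay

    @property
    def gaps(self) -> frozenset[str]:
        return frozenset(r for r, prots in self.assignments.items() if not prots)

    def to_dict(self) -> dict:
        return {
            "template": self.template.to_dict(),
            "assignments": {
                r: [p.to_dict() for p in prots] for r, prots in self.assignments.items()
            },
            "unplaced": [p.to_dict() for p in self.unplaced],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Pathway":
        return cls(
            template=PathwayTemplate.from_dict(d["template"]),
            assignments={
                r: [AnnotatedProtein.from_dict(p) for p in prots]
                for r, prots in d["assignments"].items()
            },
            unplaced=[AnnotatedProtein.from_dict(p) for p in d.get("unplaced", ())],
        )


def build_pathway(
    template: PathwayTemplate, annotations: Iterable[AnnotatedProtein]
) -> Pathway:
    """Attach each annotation to every reaction sharing an EC number.

    Proteins with no matching reaction are listed as unplaced.  Ordering is
    deterministic: reactions keep template order; proteins sort by
    descending MS, then CS, then query id.
    """
    annotations = list(annotations)
    assignments: dict[str, list[AnnotatedProtein]] = {
        r.reaction_id: [] for r in template.reactions
    }
    placed: set[int] = set()
    for reaction in template.reactions:
        ecs = set(reaction.ec_numbers)
        for i, ann in enumerate(annotations):
            if ecs & set(ann.ec_numbers):
                assignments[reaction.reaction_id].append(ann)
                placed.add(i)
    for prots in assignments.values():
        prots.sort(key=lambda a: (-a.ms, -a.cs, a.query_id, a.function_label))
    unplaced = [a for i, a in enumerate(annotations) if i not in placed]
    unplaced.sort(key=lambda a: (a.query_id, a.function_label))
    return Pathway(template=template, assignments=assignments, unplaced=unplaced)


@dataclass
class PathwayStats:
    per_sub_pathway: pd.DataFrame  # reaction/gap counts, proteins per reaction
    per_species: pd.DataFrame  # template genes vs annotated query proteins
    n_reactions: int
    n_gaps: int
    n_distinct_proteins: int

    def to_dict(self) -> dict:
        return {
            "n_reactions": self.n_reactions,
            "n_gaps": self.n_gaps,
            "n_distinct_proteins": self.n_distinct_proteins,
            "per_sub_pathway": self.per_sub_pathway.to_dict(orient="records"),
            "per_species": self.per_species.to_dict(orient="records"),
        }


def pathway_stats(pathway: Pathway) -> PathwayStats:
    """Per-sub-pathway reaction/gap/protein statistics and the per-species
    template-vs-annotated counts (the shape of a reconstruction summary
    table: number of template sequences / number of query sequences
    annotated from each species)."""
    sub_rows = []
    sub_names: list[str] = []
    for r in pathway.template.reactions:
        if r.sub_pathway not in sub_names:
            sub_names.append(r.sub_pathway)
    for sub in sub_names:
        reactions = [r for r in pathway.template.reactions if r.sub_pathway == sub]
        gap_ids = pathway.gaps
        gaps = [r for r in reactions if r.reaction_id in gap_ids]
        counts = [
            len(pathway.assignments[r.reaction_id])
            for r in reactions
            if r.reaction_id not in gap_ids
        ]
        distinct = {
            p.query_id for r in reactions for p in pathway.assignments[r.reaction_id]
        }
        sub_rows.append(
            {
                "sub_pathway": sub,
                "n_reactions": len(reactions),
                "n_gaps": len(gaps),
                "mean_proteins_per_reaction": float(statistics.mean(counts)) if counts else 0.0,
                "median_proteins_per_reaction": float(statistics.median(counts)) if counts else 0.0,
                "n_distinct_proteins": len(distinct),
            }
        )

    all_annotations = {
        id(p): p for prots in pathway.assignments.values() for p in prots
    }
    all_annotations.update({id(p): p for p in pathway.unplaced})
    species_rows = []
    species_order: list[str] = list(pathway.template.species)
    for sp in species_order:
        annotated = {
            a.query_id
            for a in all_annotations.values()
            if any(e.template_species == sp for e in a.candidate.evidence)
        }
        species_rows.append(
            {
                "species": sp,
                "n_template_genes": len(pathway.template.genes_of(sp)),
                "n_query_proteins_annotated": len(annotated),
            }
        )
    distinct_all = {a.query_id for a in all_annotations.values()}
    return PathwayStats(
        per_sub_pathway=pd.DataFrame(
            sub_rows,
            columns=[
                "sub_pathway", "n_reactions", "n_gaps",
                "mean_proteins_per_reaction", "median_proteins_per_reaction",
                "n_distinct_proteins",
            ],
        ),
        per_species=pd.DataFrame(
            species_rows,
            columns=["species", "n_template_genes", "n_query_proteins_annotated"],
        ),
        n_reactions=len(pathway.template.reactions),
        n_gaps=len(pathway.gaps),
        n_distinct_proteins=len(distinct_all),
    )


@dataclass
class ValidationReport:
    """Outcome of matching a curated known-gene set to the annotation."""

    matched_pairs: pd.DataFrame  # known_id, query_id, pident, evalue
    n_known: int
    n_matched_genes: int
    n_matched_proteins: int
    fraction_validated_in_bc: float

    def to_dict(self) -> dict:
        return {
            "n_known": self.n_known,
            "n_matched_genes": self.n_matched_genes,
            "n_matched_proteins": self.n_matched_proteins,
            "fraction_validated_in_bc": self.fraction_validated_in_bc,
            "matched_pairs": self.matched_pairs.to_dict(orient="records"),
        }


def validate_against_known(
    annotations: Sequence[AnnotatedProtein],
    known_genes: Sequence[SequenceRecord],
    query_proteome,
    scheme: ScoringScheme | None = None,
    max_evalue: float = 1e-10,
    min_pident: float = 90.0,
) -> ValidationReport:
    """Match curated known proteins to annotated proteins.

    A known gene matches an annotated protein iff their best local
    alignment satisfies E-value <= max_evalue and percent identity >=
    min_pident (both inclusive).  Matched annotations get validated=True.
    """
    annotations = list(annotations)
    if not known_genes:
        warnings.warn("empty known-gene set: validation report is empty")
        return ValidationReport(
            matched_pairs=pd.DataFrame(columns=["known_id", "query_id", "pident", "evalue"]),
            n_known=0, n_matched_genes=0, n_matched_proteins=0,
            fraction_validated_in_bc=float("nan"),
        )
    scheme = scheme or ScoringScheme.protein_default()
    qidx = query_proteome if isinstance(query_proteome, Mapping) else index_by_id(query_proteome)
    target_ids = sorted({a.query_id for a in annotations})
    db_size = sum(len(qidx[t]) for t in target_ids)
    pairs = []
    matched_proteins: set[str] = set()
    matched_genes: set[str] = set()
    for kg in known_genes:
        for tid in target_ids:
            hit = local_align(kg, qidx[tid], scheme, database_residues=db_size)
            if hit is None:
                continue
            if hit.evalue <= max_evalue and hit.pident >= min_pident:
                pairs.append((kg.id, tid, hit.pident, hit.evalue))
                matched_genes.add(kg.id)
                matched_proteins.add(tid)
    for ann in annotations:
        if ann.query_id in matched_proteins:
            ann.validated = True
    validated = [a for a in annotations if a.validated]
    frac_bc = (
        sum(a.region in ("B", "C") for a in validated) / len(validated)
        if validated
        else float("nan")
    )
    return ValidationReport(
        matched_pairs=pd.DataFrame(pairs, columns=["known_id", "query_id", "pident", "evalue"]),
        n_known=len(known_genes),
        n_matched_genes=len(matched_genes),
        n_matched_proteins=len(matched_proteins),
        fraction_validated_in_bc=frac_bc,
    )
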