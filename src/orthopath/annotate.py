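"""Two-pass reciprocal-best-hit ortholog annotation.

For every template gene, a first pass searches the query proteome; the
best filtered hit is tested for reciprocity by a second pass back against
the template proteome.  Reciprocal best hits receive match-quality weight
H = 1.  Remaining filtered first-pass hits are kept with H = 0.5 only if
their own best second-pass hit carries a function label identical (after
case-folding and whitespace normalization) to the template gene's.
All filters (E-value, percent identity, query coverage) are inclusive and
are enforced on both passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .align import (
    AlignmentHit,
    ScoringScheme,
    best_hits,
    estimate_evalue,
    hit_sort_key,
    local_align,
    raw_local_score,
)
from .records import (
    PathwayTemplate,
    SequenceRecord,
    TemplateGene,
    index_by_id,
    normalize_function,
)


@dataclass(frozen=True)
class FilterConfig:
    """Inclusive hit-retention thresholds (E-value, identity %, coverage %)."""

    max_evalue: float = 1e-10
    min_pident: float = 60.0
    min_qcov: float = 80.0

    def __post_init__(self) -> None:
        if self.max_evalue < 0:
            raise ValueError("max_evalue must be non-negative")
        if not (0 <= self.min_pident <= 100 and 0 <= self.min_qcov <= 100):
            raise ValueError("percent thresholds must lie in [0, 100]")

    def passes(self, hit: AlignmentHit) -> bool:
        return (
            hit.evalue <= self.max_evalue
            and hit.pident >= self.min_pident
            and hit.qcov >= self.min_qcov
        )


def apply_filters(hits: Iterable[AlignmentHit], config: FilterConfig) -> list[AlignmentHit]:
    """Keep exactly the hits passing all three inclusive thresholds, in order."""
    return [h for h in hits if config.passes(h)]


@dataclass(frozen=True)
class EvidenceItem:
    """One template species' support for a (query, function) annotation."""

    template_species: str
    template_gene: TemplateGene
    hit_kind: str  # "rbh" | "secondary_confirmed"
    H: float
    F: float
    forward_hit: AlignmentHit | None = None
    reverse_hit: AlignmentHit | None = None

    def __post_init__(self) -> None:
        if self.hit_kind not in ("rbh", "secondary_confirmed"):
            raise ValueError(f"unknown hit_kind {self.hit_kind!r}")
        if (self.hit_kind == "rbh") != (self.H == 1.0):
            raise ValueError("hit_kind=rbh iff H=1.0")
        if self.H not in (1.0, 0.5) or self.F not in (1.0, 0.5):
            raise ValueError("H and F weights must be 1.0 or 0.5")
        if (self.F == 1.0) != (self.template_gene.clarity == "clear"):
            raise ValueError("F=1.0 iff the template gene's function is clear")

    @property
    def weight(self) -> float:
        return self.H * self.F

    def to_dict(self) -> dict:
        return {
            "template_species": self.template_species,
            "template_gene": self.template_gene.to_dict(),
            "hit_kind": self.hit_kind,
            "H": self.H,
            "F": self.F,
            "forward_hit": self.forward_hit.to_dict() if self.forward_hit else None,
            "reverse_hit": self.reverse_hit.to_dict() if self.reverse_hit else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvidenceItem":
        return cls(
            template_species=d["template_species"],
            template_gene=TemplateGene.from_dict(d["template_gene"]),
            hit_kind=d["hit_kind"],
            H=d["H"],
            F=d["F"],
            forward_hit=AlignmentHit.from_dict(d["forward_hit"]) if d.get("forward_hit") else None,
            reverse_hit=AlignmentHit.from_dict(d["reverse_hit"]) if d.get("reverse_hit") else None,
        )


@dataclass(frozen=True)
class AnnotationCandidate:
    """A query protein with one assigned function and per-species evidence."""

    query_id: str
    function_label: str
    ec_numbers: tuple[str, ...]
    evidence: tuple[EvidenceItem, ...]

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("candidate must carry at least one evidence item")
        labels = {normalize_function(e.template_gene.function_label) for e in self.evidence}
        if len(labels) != 1:
            raise ValueError("evidence items must share one function label")
        species = [e.template_species for e in self.evidence]
        if len(species) != len(set(species)):
            raise ValueError("at most one evidence item per template species")
        object.__setattr__(self, "ec_numbers", tuple(self.ec_numbers))
        object.__setattr__(self, "evidence", tuple(self.evidence))

    @property
    def n_m(self) -> int:
        return len(self.evidence)

    def to_dict(self) -> dict:
        return {
            "query_id": self.query_id,
            "function_label": self.function_label,
            "ec_numbers": list(self.ec_numbers),
            "evidence": [e.to_dict() for e in self.evidence],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnnotationCandidate":
        return cls(
            query_id=d["query_id"],
            function_label=d["function_label"],
            ec_numbers=tuple(d["ec_numbers"]),
            evidence=tuple(EvidenceItem.from_dict(e) for e in d["evidence"]),
        )


class HitSource:
    """Lazily computed (and cached) first- and second-pass hit lists.

    Precomputed hit tables (e.g. parsed from real BLAST tabular output) may
    be supplied; anything missing is computed with the internal aligner.
    """

    def __init__(
        self,
        query_proteome: Mapping[str, SequenceRecord],
        template_proteomes: Mapping[str, Mapping[str, SequenceRecord]],
        scheme: ScoringScheme | None = None,
        forward: Mapping[str, Mapping[str, Sequence[AlignmentHit]]] | None = None,
        reverse: Mapping[str, Mapping[str, Sequence[AlignmentHit]]] | None = None,
        prefilter_evalue: float | None = None,
    ) -> None:
        self.query_proteome = query_proteome
        self.template_proteomes = template_proteomes
        self.scheme = scheme or ScoringScheme.protein_default()
        # hits above this E-value are dropped before traceback; safe when it
        # equals the downstream FilterConfig's inclusive max_evalue
        self.prefilter_evalue = prefilter_evalue
        self._forward: dict[tuple[str, str], list[AlignmentHit]] = {}
        self._reverse: dict[tuple[str, str], list[AlignmentHit]] = {}
        if forward:
            for sp, per_gene in forward.items():
                for gid, hits in per_gene.items():
                    self._forward[(sp, gid)] = sorted(hits, key=hit_sort_key)
        if reverse:
            for sp, per_query in reverse.items():
                for qid, hits in per_query.items():
                    self._reverse[(sp, qid)] = sorted(hits, key=hit_sort_key)
        self._query_db_size = sum(len(r) for r in query_proteome.values())

    def _align_all(self, query: SequenceRecord, subjects, db_size: int) -> list[AlignmentHit]:
        hits = []
        for rec in subjects:
            if self.prefilter_evalue is not None:
                score = raw_local_score(query, rec, self.scheme)
                if score <= 0 or estimate_evalue(
                    int(round(score)), len(query), db_size, self.scheme
                ) > self.prefilter_evalue:
                    continue
            h = local_align(query, rec, self.scheme, database_residues=db_size)
            if h is not None:
                hits.append(h)
        hits.sort(key=hit_sort_key)
        return hits

    def forward_hits(self, species: str, gene_id: str) -> list[AlignmentHit]:
        """Template gene vs the query proteome, sorted."""
        key = (species, gene_id)
        if key not in self._forward:
            gene_rec = self.template_proteomes[species].get(gene_id)
            if gene_rec is None:
                raise LookupError(
                    f"template gene {gene_id!r} absent from the {species} proteome"
                )
            self._forward[key] = self._align_all(
                gene_rec, self.query_proteome.values(), self._query_db_size
            )
        return self._forward[key]

    def reverse_hits(self, species: str, query_id: str) -> list[AlignmentHit]:
        """Query protein vs the template proteome of one species, sorted."""
        key = (species, query_id)
        if key not in self._reverse:
            qrec = self.query_proteome.get(query_id)
            if qrec is None:
                raise LookupError(f"query protein {query_id!r} not found")
            proteome = self.template_proteomes[species]
            db_size = sum(len(r) for r in proteome.values())
            self._reverse[key] = self._align_all(qrec, proteome.values(), db_size)
        return self._reverse[key]


def _as_index(records) -> dict[str, SequenceRecord]:
    if isinstance(records, Mapping):
        return dict(records)
    return index_by_id(records)


def find_rbh(
    template_gene: TemplateGene,
    template_proteome,
    query_proteome,
    config: FilterConfig | None = None,
    scheme: ScoringScheme | None = None,
    source: HitSource | None = None,
) -> tuple[str, EvidenceItem] | None:
    """Reciprocal-best-hit detection for one template gene.

    Returns (query_id, evidence with H=1) when the best filtered
    first-pass hit is confirmed by the second pass, else None.
    """
    config = config or FilterConfig()
    if source is None:
        qidx = _as_index(query_proteome)
        tidx = _as_index(template_proteome)
        source = HitSource(
            qidx, {template_gene.species: tidx}, scheme,
            prefilter_evalue=config.max_evalue,
        )
    if template_gene.gene_id not in source.template_proteomes[template_gene.species]:
        raise LookupError(
            f"template gene {template_gene.gene_id!r} absent from the "
            f"{template_gene.species} proteome"
        )
    forward = apply_filters(source.forward_hits(template_gene.species, template_gene.gene_id), config)
    if not forward:
        return None
    best = forward[0]
    reverse = apply_filters(source.reverse_hits(template_gene.species, best.subject_id), config)
    if reverse and reverse[0].subject_id == template_gene.gene_id:
        evidence = EvidenceItem(
            template_species=template_gene.species,
            template_gene=template_gene,
            hit_kind="rbh",
            H=1.0,
            F=template_gene.clarity_weight,
            forward_hit=best,
            reverse_hit=reverse[0],
        )
        return best.subject_id, evidence
    return None


def assign_functions(
    template: PathwayTemplate,
    template_proteomes: Mapping[str, Iterable[SequenceRecord] | Mapping[str, SequenceRecord]],
    query_proteome,
    config: FilterConfig | None = None,
    scheme: ScoringScheme | None = None,
    forward_hits=None,
    reverse_hits=None,
) -> list[AnnotationCandidate]:
    """Assign template-gene functions to query proteins across all species.

    Per (query, function, species) at most one evidence item is kept (the
    one with larger H, then larger forward bitscore); candidates group
    evidence by (query_id, normalized function label).
    """
    config = config or FilterConfig()
    qidx = _as_index(query_proteome)
    tidx = {sp: _as_index(p) for sp, p in template_proteomes.items()}
    source = HitSource(
        qidx, tidx, scheme, forward=forward_hits, reverse=reverse_hits,
        prefilter_evalue=config.max_evalue,
    )

    genes_by_id = {
        sp: {g.gene_id: g for g in template.genes_of(sp)} for sp in template.species
    }
    # strongest evidence per (query, function, species)
    chosen: dict[tuple[str, str, str], EvidenceItem] = {}

    for species in template.species:
        for gene in template.genes_of(species):
            forward = apply_filters(source.forward_hits(species, gene.gene_id), config)
            if not forward:
                continue
            best = forward[0]
            best_reverse = apply_filters(source.reverse_hits(species, best.subject_id), config)
            rbh_confirmed = bool(best_reverse) and best_reverse[0].subject_id == gene.gene_id
            for hit in forward:
                qid = hit.subject_id
                if qid == best.subject_id and rbh_confirmed:
                    item = EvidenceItem(
                        template_species=species, template_gene=gene,
                        hit_kind="rbh", H=1.0, F=gene.clarity_weight,
                        forward_hit=hit, reverse_hit=best_reverse[0],
                    )
                else:
                    reverse = apply_filters(source.reverse_hits(species, qid), config)
                    if not reverse:
                        continue
                    partner = genes_by_id[species].get(reverse[0].subject_id)
                    if partner is None or normalize_function(partner.function_label) != normalize_function(gene.function_label):
                        continue
                    item = EvidenceItem(
                        template_species=species, template_gene=gene,
                        hit_kind="secondary_confirmed", H=0.5, F=gene.clarity_weight,
                        forward_hit=hit, reverse_hit=reverse[0],
                    )
                key = (qid, normalize_function(gene.function_label), species)
                prev = chosen.get(key)
                if prev is None or _evidence_rank(item) > _evidence_rank(prev):
                    chosen[key] = item

    grouped: dict[tuple[str, str], list[EvidenceItem]] = {}
    for (qid, label, _species), item in sorted(chosen.items()):
        grouped.setdefault((qid, label), []).append(item)

    candidates = []
    for (qid, _label), items in sorted(grouped.items()):
        items.sort(key=lambda e: e.template_species)
        canonical = max(items, key=_evidence_rank).template_gene.function_label
        ecs = sorted({ec for e in items for ec in e.template_gene.ec_numbers})
        candidates.append(
            AnnotationCandidate(
                query_id=qid, function_label=canonical,
                ec_numbers=tuple(ecs), evidence=tuple(items),
            )
        )
    return candidates


def _evidence_rank(item: EvidenceItem) -> tuple:
    bits = item.forward_hit.bitscore if item.forward_hit else 0.0
    return (item.H, bits)
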