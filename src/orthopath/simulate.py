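"""Seeded synthetic scenario generator with a ground-truth manifest.

Emulates the study design the pipeline targets: a query proteome searched
against several well-annotated template species.  Per ortholog family an
ancestral protein is drawn and mutated independently into each template
species' gene and into the query ortholog at a controlled identity, so
that true orthologs always clear the default E-value/identity/coverage
filters while decoys (25-30% identity) never do.  Recent duplicates
("paralogs") of the query ortholog exercise the second-pass H=0.5 path;
unclear-function families exercise F=0.5; reactions with no gene family
are planted metabolic gaps.  Transcripts are random synonymous
back-translations; probes are exact or one-mismatch 60-mers; expression
tables carry planted monotone (>=2-fold) patterns for starch-synthesis
families and flat patterns for the rest.

Everything is deterministic per seed (one integer RNG stream, no
float-dependent branching), and every expectation recorded in the
TruthManifest holds by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .align import ScoringScheme, substitution_score
from .records import PathwayTemplate, ReactionDef, SequenceRecord, TemplateGene

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
BASES = "ACGT"

_EC_PREFIX = {
    "calvin_cycle": "4.1.2",
    "sucrose_synthesis": "2.4.1",
    "starch_synthesis": "2.7.7",
    "other": "9.9.9",
}

# BLOSUM62-plausible replacements: non-identical residues scoring >= 0
# against the original (fallback: every other residue).
_scheme = ScoringScheme.protein_default()
PLAUSIBLE: dict[str, tuple[str, ...]] = {}
for _a in AMINO_ACIDS:
    _cands = tuple(
        b for b in AMINO_ACIDS if b != _a and substitution_score(_a, b, _scheme) >= 0
    )
    PLAUSIBLE[_a] = _cands or tuple(b for b in AMINO_ACIDS if b != _a)

_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(standard_dna_table.forward_table.items()):
    _CODONS.setdefault(_aa, ())
    _CODONS[_aa] = _CODONS[_aa] + (_codon,)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic scenario."""

    seed: int = 1
    species: tuple[str, ...] = ("arabidopsis", "rice", "maize", "castor_bean", "potato")
    n_families: int = 30
    n_decoys: int = 30
    protein_length: tuple[int, int] = (200, 400)
    ortholog_identity: tuple[float, float] = (0.80, 0.95)
    conserved_identity_floor: float = 0.85  # paralog-carrying families
    decoy_identity: tuple[float, float] = (0.25, 0.30)
    n_paralogs: int = 5
    paralog_identity: float = 0.98
    unclear_fraction: float = 0.2
    n_gap_reactions: int = 3
    n_known_genes: int = 18
    probes_per_gene: int = 1
    probe_length: int = 60
    n_decoy_probes: int = 10
    n_extra_template_proteins: int = 3
    conditions: tuple[str, ...] = ("fibrous", "developing", "mature")
    induced_pattern: tuple[float, ...] = (12.0, 30.0, 70.0)  # >= 2-fold, monotone
    flat_pattern: tuple[float, ...] = (20.0, 24.0, 22.0)  # < 2-fold

    @property
    def n_species(self) -> int:
        return len(self.species)

    def validate(self) -> None:
        if self.n_species < 1 or self.n_families < 1:
            raise ValueError("need at least one species and one family")
        lo, hi = self.ortholog_identity
        if not (0 < lo <= hi <= 1):
            raise ValueError("ortholog identity range must lie in (0, 1]")
        dlo, dhi = self.decoy_identity
        if not (0 < dlo <= dhi < lo):
            raise ValueError("decoy identity ceiling must lie below the ortholog floor")
        if not (lo <= self.conserved_identity_floor <= hi):
            raise ValueError("conserved_identity_floor must lie inside the ortholog range")
        if not (0 < self.paralog_identity <= 1):
            raise ValueError("paralog identity must lie in (0, 1]")
        if not (0 <= self.unclear_fraction <= 1):
            raise ValueError("unclear fraction must lie in [0, 1]")
        if self.n_known_genes > self.n_families:
            raise ValueError("cannot plant more known genes than families")
        if self.n_paralogs > (self.n_families + 1) // 2:
            raise ValueError("paralog families must be a subset of the conserved families")
        if len(self.conditions) != len(self.induced_pattern) or len(self.conditions) != len(self.flat_pattern):
            raise ValueError("expression patterns must match the condition labels")
        if max(self.induced_pattern) / max(min(self.induced_pattern), 1.0) < 2.0:
            raise ValueError("induced pattern must reach two-fold")
        if max(self.flat_pattern) / max(min(self.flat_pattern), 1.0) >= 2.0:
            raise ValueError("flat pattern must stay below two-fold")


@dataclass
class TruthManifest:
    """Ground truth for every generated record, consistent by construction."""

    config: dict
    families: list[dict]
    expected_rbh_pairs: list[list]  # [species, template_gene_id, query_id]
    expected_assignments: list[dict]
    expected_gaps: list[str]
    decoy_ids: list[str]
    known_gene_ids: list[str]
    expected_validated_query_ids: list[str]
    expected_probe_map: dict[str, list[str]]
    expected_filter_passing_genes: list[str]
    conditions: list[str]

    def to_dict(self) -> dict:
        return self.__dict__.copy()

    @classmethod
    def from_dict(cls, d: dict) -> "TruthManifest":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class ScenarioBundle:
    """Paths of one generated scenario."""

    root: Path
    query_fasta: Path
    template_fastas: dict[str, Path]
    pathway_template: Path
    known_genes: Path
    gene_nucleotides: Path
    probes: Path
    expression: Path
    manifest: Path


def mutate_sequence(
    parent: SequenceRecord,
    target_identity: float,
    rng: np.random.Generator,
    new_id: str,
    species: str = "",
    forbidden: Mapping[int, set[str]] | None = None,
    positions: Sequence[int] | None = None,
) -> SequenceRecord:
    """Substitute residues so realized identity to the parent is exactly
    round(target_identity * L) / L.

    Replacements are substitution-matrix-plausible (score >= 0 against the
    original where possible) and may be constrained per position via
    ``forbidden`` (used to rule out back-mutations).
    """
    if not (0 < target_identity <= 1):
        raise ValueError("target identity must lie in (0, 1]")
    L = len(parent)
    n_mut = L - int(target_identity * L + 0.5)
    if target_identity < 1.0 / L:
        raise ValueError(f"target identity {target_identity} below 1/length")
    residues = list(parent.residues)
    alphabet = parent.alphabet
    if positions is None:
        positions = sorted(int(p) for p in rng.choice(L, size=n_mut, replace=False))
    else:
        positions = sorted(positions)
        if len(positions) != n_mut:
            raise ValueError("explicit positions must match the mutation count")
    for pos in positions:
        orig = residues[pos]
        if alphabet == "protein":
            cands = list(PLAUSIBLE[orig])
        else:
            cands = [b for b in BASES if b != orig]
        if forbidden and pos in forbidden:
            kept = [c for c in cands if c not in forbidden[pos]]
            if not kept:
                pool = AMINO_ACIDS if alphabet == "protein" else BASES
                kept = [c for c in pool if c != orig and c not in forbidden[pos]]
            cands = kept or cands
        residues[pos] = cands[int(rng.integers(len(cands)))]
    return SequenceRecord(
        id=new_id, residues="".join(residues), species=species, alphabet=alphabet
    )


def _random_protein(rng: np.random.Generator, length: int, rec_id: str, species: str = "") -> SequenceRecord:
    idx = rng.integers(0, len(AMINO_ACIDS), size=length)
    return SequenceRecord(
        id=rec_id, residues="".join(AMINO_ACIDS[i] for i in idx),
        species=species, alphabet="protein",
    )


def back_translate(protein: SequenceRecord, rng: np.random.Generator, new_id: str | None = None) -> SequenceRecord:
    """Random synonymous back-translation (uniform codon choice per site)."""
    codons = []
    for aa in protein.residues:
        options = _CODONS[aa]
        codons.append(options[int(rng.integers(len(options)))])
    return SequenceRecord(
        id=new_id or protein.id, residues="".join(codons),
        species=protein.species, alphabet="nucleotide",
    )


def _identity_percent(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


def generate_scenario(config: ScenarioConfig, outdir: str | Path) -> tuple[ScenarioBundle, TruthManifest]:
    """Write the full synthetic file bundle plus its truth manifest."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    (outdir / "templates").mkdir(parents=True, exist_ok=True)

    sub_cycle = ("calvin_cycle", "sucrose_synthesis", "starch_synthesis")
    unclear_stride = int(round(1 / config.unclear_fraction)) if config.unclear_fraction > 0 else 0
    # conserved (all-species) families sit at even indices; paralogs go to
    # the first n_paralogs of them, where identities are drawn from the
    # conserved floor so the duplicate keeps a safety margin over the
    # 60/80 thresholds in every template species.
    paralog_families = {2 * k for k in range(config.n_paralogs)}

    families: list[dict] = []
    template_proteomes: dict[str, list[SequenceRecord]] = {sp: [] for sp in config.species}
    template_genes: list[TemplateGene] = []
    reactions: list[ReactionDef] = []
    query_records: list[SequenceRecord] = []
    nucleotide_genes: list[SequenceRecord] = []
    known_genes: list[SequenceRecord] = []
    expected_rbh: list[list] = []
    expected_assignments: list[dict] = []
    expected_probe_map: dict[str, list[str]] = {}
    probe_records: list[SequenceRecord] = []
    expression_rows: dict[str, tuple[float, ...]] = {}
    expected_passing: list[str] = []
    expected_validated: list[str] = []

    lo_pct = int(round(config.ortholog_identity[0] * 100))
    hi_pct = int(round(config.ortholog_identity[1] * 100))
    floor_pct = int(round(config.conserved_identity_floor * 100))

    def draw_identity(conserved: bool) -> float:
        lo = floor_pct if conserved else lo_pct
        return int(rng.integers(lo, hi_pct + 1)) / 100.0

    for i in range(config.n_families):
        sub = sub_cycle[i % 3]
        ec = f"{_EC_PREFIX[sub]}.{i + 1}"
        unclear = unclear_stride > 0 and i % unclear_stride == 1
        label = f"{sub.replace('_', ' ')} enzyme {i:03d}" + (" putative" if unclear else "")
        length = int(rng.integers(*config.protein_length))
        ancestor = _random_protein(rng, length, f"anc_{i:03d}")

        if i % 2 == 0 or config.n_species <= 2:
            present = list(config.species)
        else:
            size = int(rng.integers(2, config.n_species))  # 2..n_species-1
            chosen = rng.choice(config.n_species, size=size, replace=False)
            present = [config.species[j] for j in sorted(int(c) for c in chosen)]

        conserved = i in paralog_families
        per_species: dict[str, SequenceRecord] = {}
        for sp in present:
            gid = f"{sp[:3]}{i:04d}"
            rec = mutate_sequence(ancestor, draw_identity(conserved), rng, gid, species=sp)
            per_species[sp] = rec
            template_proteomes[sp].append(rec)
            template_genes.append(
                TemplateGene(
                    species=sp, gene_id=gid, function_label=label,
                    ec_numbers=(ec,), clarity="unclear" if unclear else "clear",
                )
            )

        qid = f"{i + 1:06d}_{i + 1:06d}"
        query = mutate_sequence(ancestor, draw_identity(conserved), rng, qid, species="query")
        query_records.append(query)
        nucleotide_genes.append(back_translate(query, rng))

        reactions.append(
            ReactionDef(
                reaction_id=f"R{i + 1:03d}", ec_numbers=(ec,),
                substrates=(f"M{i:03d}",), products=(f"M{i + 1:03d}",),
                sub_pathway=sub,
            )
        )

        F = 0.5 if unclear else 1.0
        n_m = len(present)
        for sp in present:
            expected_rbh.append([sp, per_species[sp].id, qid])
        expected_assignments.append(
            {
                "query_id": qid,
                "function_label": label,
                "per_species": {sp: {"H": 1.0, "F": F} for sp in present},
                "n_m": n_m,
                "ms": F,
                "cs": F * n_m / config.n_species,
            }
        )

        paralog_id = None
        if conserved:
            paralog_id = f"{500001 + i:06d}_{500001 + i:06d}"
            n_mut = len(query) - int(config.paralog_identity * len(query) + 0.5)
            # mutate only ancestor-conserved sites and forbid both the
            # ortholog's and every template's residue there: the duplicate
            # can never outscore the true ortholog against any template.
            conserved_sites = [
                p for p in range(len(query)) if query.residues[p] == ancestor.residues[p]
            ]
            picked = rng.choice(len(conserved_sites), size=n_mut, replace=False)
            positions = [conserved_sites[int(p)] for p in picked]
            forbidden = {
                p: {query.residues[p]} | {rec.residues[p] for rec in per_species.values()}
                for p in positions
            }
            paralog = mutate_sequence(
                query, config.paralog_identity, rng, paralog_id,
                species="query", forbidden=forbidden, positions=positions,
            )
            query_records.append(paralog)
            nucleotide_genes.append(back_translate(paralog, rng))
            expected_assignments.append(
                {
                    "query_id": paralog_id,
                    "function_label": label,
                    "per_species": {sp: {"H": 0.5, "F": F} for sp in present},
                    "n_m": n_m,
                    "ms": 0.5 * F,
                    "cs": 0.5 * F * n_m / config.n_species,
                }
            )

        if i < config.n_known_genes:
            kid = f"KG{i:03d}"
            known_genes.append(
                SequenceRecord(id=kid, residues=query.residues, species="genbank", alphabet="protein")
            )
            expected_validated.append(qid)
            if paralog_id is not None:
                expected_validated.append(paralog_id)

        # probes: exact or one-mismatch substrings of the transcript
        transcript = nucleotide_genes[-1] if paralog_id is None else nucleotide_genes[-2]
        probe_ids = []
        for j in range(config.probes_per_gene):
            start = int(rng.integers(0, len(transcript) - config.probe_length + 1))
            sub_seq = transcript.residues[start : start + config.probe_length]
            pid = f"pr{i:03d}_{j}"
            if (i + j) % 2 == 1:
                mid = config.probe_length // 2
                orig = sub_seq[mid]
                repl = [b for b in BASES if b != orig][int(rng.integers(3))]
                sub_seq = sub_seq[:mid] + repl + sub_seq[mid + 1 :]
            probe_records.append(
                SequenceRecord(id=pid, residues=sub_seq, species="array", alphabet="nucleotide")
            )
            probe_ids.append(pid)
            pattern = config.induced_pattern if sub == "starch_synthesis" else config.flat_pattern
            scale = 1.0 + 0.5 * (i % 3)
            expression_rows[pid] = tuple(v * scale for v in pattern)
        expected_probe_map[query.gene_id] = sorted(probe_ids)
        if sub == "starch_synthesis":
            expected_passing.append(query.gene_id)

        families.append(
            {
                "index": i,
                "reaction_id": f"R{i + 1:03d}",
                "ec": ec,
                "function_label": label,
                "clarity": "unclear" if unclear else "clear",
                "sub_pathway": sub,
                "species": present,
                "template_gene_ids": {sp: per_species[sp].id for sp in present},
                "query_id": qid,
                "gene_id": query.gene_id,
                "paralog_id": paralog_id,
                "expected_n_m": n_m,
                "expected_F": F,
            }
        )

    # planted metabolic gaps: reactions whose EC no family carries
    expected_gaps = []
    for k in range(config.n_gap_reactions):
        sub = sub_cycle[k % 3]
        rid = f"RG{k + 1:02d}"
        reactions.append(
            ReactionDef(
                reaction_id=rid,
                ec_numbers=(f"{_EC_PREFIX[sub]}.{config.n_families + k + 1}",),
                substrates=(f"MG{k:02d}",), products=(f"MG{k + 1:02d}",),
                sub_pathway=sub,
            )
        )
        expected_gaps.append(rid)

    # decoys: far below the identity filter, derived from family ancestors
    dlo = int(round(config.decoy_identity[0] * 100))
    dhi = int(round(config.decoy_identity[1] * 100))
    decoy_ids = []
    for j in range(config.n_decoys):
        fam = families[j % config.n_families]
        length = int(rng.integers(*config.protein_length))
        ancestor = _random_protein(rng, length, "tmp")
        target = int(rng.integers(dlo, dhi + 1)) / 100.0
        did = f"{900001 + j:06d}_xxxxxx"
        decoy = mutate_sequence(ancestor, target, rng, did, species="query")
        query_records.append(decoy)
        decoy_ids.append(did)

    # unrelated background proteins in each template proteome
    for sp in config.species:
        for k in range(config.n_extra_template_proteins):
            length = int(rng.integers(*config.protein_length))
            template_proteomes[sp].append(
                _random_protein(rng, length, f"{sp[:3]}_bg{k:02d}", species=sp)
            )

    # decoy probes: random 60-mers, flat low expression
    for k in range(config.n_decoy_probes):
        idx = rng.integers(0, 4, size=config.probe_length)
        pid = f"prdec{k:02d}"
        probe_records.append(
            SequenceRecord(
                id=pid, residues="".join(BASES[i] for i in idx),
                species="array", alphabet="nucleotide",
            )
        )
        expression_rows[pid] = tuple(5.0 for _ in config.conditions)

    template = PathwayTemplate(
        name="starch_biosynthesis_synthetic",
        reactions=tuple(reactions),
        template_genes=tuple(template_genes),
    )

    from .formats import write_fasta, write_pathway_template

    bundle = ScenarioBundle(
        root=outdir,
        query_fasta=outdir / "query.faa",
        template_fastas={sp: outdir / "templates" / f"{sp}.faa" for sp in config.species},
        pathway_template=outdir / "pathway_template.json",
        known_genes=outdir / "known_genes.faa",
        gene_nucleotides=outdir / "genes.fna",
        probes=outdir / "probes.fna",
        expression=outdir / "expression.tsv",
        manifest=outdir / "manifest.json",
    )
    write_fasta(query_records, bundle.query_fasta)
    for sp in config.species:
        write_fasta(template_proteomes[sp], bundle.template_fastas[sp])
    write_pathway_template(template, bundle.pathway_template)
    write_fasta(known_genes, bundle.known_genes)
    write_fasta(nucleotide_genes, bundle.gene_nucleotides)
    write_fasta(probe_records, bundle.probes)
    with open(bundle.expression, "w") as fh:
        fh.write("probe_id\t" + "\t".join(config.conditions) + "\n")
        for pid in expression_rows:
            fh.write(pid + "\t" + "\t".join(f"{v:g}" for v in expression_rows[pid]) + "\n")

    manifest = TruthManifest(
        config={
            "seed": config.seed,
            "species": list(config.species),
            "n_families": config.n_families,
            "n_decoys": config.n_decoys,
            "n_paralogs": config.n_paralogs,
            "n_gap_reactions": config.n_gap_reactions,
            "n_known_genes": config.n_known_genes,
        },
        families=families,
        expected_rbh_pairs=expected_rbh,
        expected_assignments=expected_assignments,
        expected_gaps=expected_gaps,
        decoy_ids=decoy_ids,
        known_gene_ids=[k.id for k in known_genes],
        expected_validated_query_ids=sorted(expected_validated),
        expected_probe_map=expected_probe_map,
        expected_filter_passing_genes=sorted(expected_passing),
        conditions=list(config.conditions),
    )
    manifest.save(bundle.manifest)
    return bundle, manifest
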