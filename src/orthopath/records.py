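"""Core domain types: sequences, template genes, and pathway templates.

The pathway template is the comparative scaffold: an ordered list of
enzymatic reactions keyed by EC number, plus the template-species genes
(with function labels and a clear/unclear clarity flag) that seed the
reciprocal-best-hit search.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")

SUB_PATHWAYS = ("calvin_cycle", "sucrose_synthesis", "starch_synthesis", "other")

_EC_RE = re.compile(r"^\d+\.\d+\.\d+\.\d+$")
# 12-digit id convention: 6-digit gene id + "_" + 6-digit transcript id,
# where an unresolved transcript is written as "xxxxxx".
_GENE_TRANSCRIPT_RE = re.compile(r"^(\d{6})_(\d{6}|x{6})$")


class FormatError(ValueError):
    """Malformed input file or record."""


def is_valid_ec(ec: str) -> bool:
    return bool(_EC_RE.match(ec))


def normalize_function(label: str) -> str:
    """Case-fold and collapse whitespace; the equality used for the
    second-pass 'identical function' rule."""
    return " ".join(label.casefold().split())


@dataclass(frozen=True)
class SequenceRecord:
    """One protein or nucleotide sequence with its species of origin."""

    id: str
    residues: str
    species: str = ""
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"sequence id {self.id!r} is empty or contains whitespace")
        if self.alphabet not in ("protein", "nucleotide"):
            raise FormatError(f"unknown alphabet {self.alphabet!r}")
        residues = self.residues.upper()
        object.__setattr__(self, "residues", residues)
        if not residues:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        allowed = PROTEIN_ALPHABET if self.alphabet == "protein" else NUCLEOTIDE_ALPHABET
        bad = set(residues) - allowed
        if bad:
            raise FormatError(
                f"record {self.id!r} has illegal {self.alphabet} residues: "
                + ",".join(sorted(bad))
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def gene_id(self) -> str:
        """Gene part of the 12-digit gene/transcript convention, else the id."""
        m = _GENE_TRANSCRIPT_RE.match(self.id)
        return m.group(1) if m else self.id

    @property
    def transcript_id(self) -> str | None:
        m = _GENE_TRANSCRIPT_RE.match(self.id)
        if m and not m.group(2).startswith("x"):
            return m.group(2)
        return None


@dataclass(frozen=True)
class TemplateGene:
    """A pathway gene of one template species, with its assigned function."""

    species: str
    gene_id: str
    function_label: str
    ec_numbers: tuple[str, ...] = ()
    clarity: str = "clear"

    def __post_init__(self) -> None:
        if self.clarity not in ("clear", "unclear"):
            raise FormatError(f"clarity must be clear/unclear, got {self.clarity!r}")
        object.__setattr__(self, "ec_numbers", tuple(self.ec_numbers))
        for ec in self.ec_numbers:
            if not is_valid_ec(ec):
                raise FormatError(
                    f"template gene {self.gene_id!r}: malformed EC number {ec!r}"
                )

    @property
    def clarity_weight(self) -> float:
        """F weight: 1 for a clearly annotated template gene, 0.5 otherwise."""
        return 1.0 if self.clarity == "clear" else 0.5

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "gene_id": self.gene_id,
            "function_label": self.function_label,
            "ec_numbers": list(self.ec_numbers),
            "clarity": self.clarity,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TemplateGene":
        return cls(
            species=d["species"],
            gene_id=d["gene_id"],
            function_label=d["function_label"],
            ec_numbers=tuple(d.get("ec_numbers", ())),
            clarity=d.get("clarity", "clear"),
        )


@dataclass(frozen=True)
class ReactionDef:
    """One template reaction: EC numbers, substrates, products, sub-pathway."""

    reaction_id: str
    ec_numbers: tuple[str, ...]
    substrates: tuple[str, ...] = ()
    products: tuple[str, ...] = ()
    sub_pathway: str = "other"

    def __post_init__(self) -> None:
        object.__setattr__(self, "ec_numbers", tuple(self.ec_numbers))
        object.__setattr__(self, "substrates", tuple(self.substrates))
        object.__setattr__(self, "products", tuple(self.products))
        if not self.ec_numbers:
            raise FormatError(f"reaction {self.reaction_id!r} has no EC number")
        for ec in self.ec_numbers:
            if not is_valid_ec(ec):
                raise FormatError(
                    f"reaction {self.reaction_id!r}: malformed EC number {ec!r}"
                )
        if self.sub_pathway not in SUB_PATHWAYS:
            raise FormatError(
                f"reaction {self.reaction_id!r}: unknown sub-pathway {self.sub_pathway!r}"
            )

    def to_dict(self) -> dict:
        return {
            "reaction_id": self.reaction_id,
            "ec_numbers": list(self.ec_numbers),
            "substrates": list(self.substrates),
            "products": list(self.products),
            "sub_pathway": self.sub_pathway,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReactionDef":
        return cls(
            reaction_id=d["reaction_id"],
            ec_numbers=tuple(d["ec_numbers"]),
            substrates=tuple(d.get("substrates", ())),
            products=tuple(d.get("products", ())),
            sub_pathway=d.get("sub_pathway", "other"),
        )


@dataclass(frozen=True)
class PathwayTemplate:
    """Reaction scaffold plus the template genes that seed the search."""

    name: str
    reactions: tuple[ReactionDef, ...]
    template_genes: tuple[TemplateGene, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactions", tuple(self.reactions))
        object.__setattr__(self, "template_genes", tuple(self.template_genes))
        ids = [r.reaction_id for r in self.reactions]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate reaction ids: {dup}")

    @property
    def reaction_ecs(self) -> frozenset[str]:
        return frozenset(ec for r in self.reactions for ec in r.ec_numbers)

    @property
    def auxiliary_genes(self) -> tuple[TemplateGene, ...]:
        """Template genes whose ECs are not all covered by the reaction list."""
        covered = self.reaction_ecs
        return tuple(
            g for g in self.template_genes if not set(g.ec_numbers) <= covered
        )

    @property
    def species(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for g in self.template_genes:
            seen.setdefault(g.species)
        return tuple(seen)

    def genes_of(self, species: str) -> tuple[TemplateGene, ...]:
        return tuple(g for g in self.template_genes if g.species == species)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "reactions": [r.to_dict() for r in self.reactions],
            "template_genes": [g.to_dict() for g in self.template_genes],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PathwayTemplate":
        return cls(
            name=d["name"],
            reactions=tuple(ReactionDef.from_dict(r) for r in d["reactions"]),
            template_genes=tuple(
                TemplateGene.from_dict(g) for g in d.get("template_genes", ())
            ),
        )


def index_by_id(records: Iterable[SequenceRecord]) -> dict[str, SequenceRecord]:
    """Index records by id, rejecting duplicates."""
    out: dict[str, SequenceRecord] = {}
    for rec in records:
        if rec.id in out:
            raise FormatError(f"duplicate sequence id {rec.id!r}")
        out[rec.id] = rec
    return out
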