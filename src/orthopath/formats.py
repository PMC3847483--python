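"""Readers and writers for every external format the pipeline touches.

FASTA (via Biopython), 12-column BLAST tabular hits, the pathway template
(TSV or JSON), expression matrices (TSV), and GraphML/JSON export of the
reconstructed pathway graph.  Readers are strict, deterministic, and
preserve input order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .align import AlignmentHit
from .records import (
    FormatError,
    PathwayTemplate,
    ReactionDef,
    SequenceRecord,
    TemplateGene,
)

BLAST_TAB_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, alphabet: str = "protein", species: str = "") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (uppercased, order preserved)."""
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        try:
            records.append(
                SequenceRecord(id=rec.id, residues=str(rec.seq), species=species, alphabet=alphabet)
            )
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    bio = [
        BioSeqRecord(Seq(r.residues), id=r.id, description="")
        for r in records
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(bio)


# ---------------------------------------------------------------------------
# BLAST tabular

def read_blast_tab(path: str | Path, query_lengths: Mapping[str, int]) -> list[AlignmentHit]:
    """Parse 12-column BLAST outfmt-6 hits.

    Query coverage is not a BLAST column; it is recomputed as
    100*(qend-qstart+1)/query_length from the supplied length mapping.
    """
    path = Path(path)
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            qseqid, sseqid = fields[0], fields[1]
            if qseqid not in query_lengths:
                raise LookupError(
                    f"{path}:{lineno}: query id {qseqid!r} missing from query-length mapping"
                )
            try:
                pident = float(fields[2])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: unparseable numeric field: {exc}") from exc
            qcov = 100.0 * (qend - qstart + 1) / query_lengths[qseqid]
            hits.append(
                AlignmentHit(
                    query_id=qseqid, subject_id=sseqid, bitscore=bitscore,
                    evalue=evalue, pident=pident, qcov=qcov,
                    qstart=qstart, qend=qend, sstart=sstart, send=send,
                )
            )
    return hits


def write_blast_tab(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits in the 12-column dialect (mismatch/gapopen as 0 when unknown)."""
    with open(path, "w") as fh:
        for h in hits:
            length = max(h.qend - h.qstart + 1, 0)
            fh.write(
                "\t".join(
                    [
                        h.query_id, h.subject_id, f"{h.pident:.2f}", str(length),
                        "0", "0", str(h.qstart), str(h.qend), str(h.sstart),
                        str(h.send), f"{h.evalue:.3g}", f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Pathway template (JSON or sectioned TSV)

def read_pathway_template(path: str | Path) -> PathwayTemplate:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
        try:
            return PathwayTemplate.from_dict(data)
        except (KeyError, FormatError) as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return _read_template_tsv(path)


def _read_template_tsv(path: Path) -> PathwayTemplate:
    """Sectioned TSV: 'pathway<TAB>name', then 'reaction' and 'gene' rows.

    reaction<TAB>id<TAB>EC;EC<TAB>substrates;...<TAB>products;...<TAB>sub_pathway
    gene<TAB>species<TAB>gene_id<TAB>function<TAB>EC;EC<TAB>clarity
    """
    name = path.stem
    reactions: list[ReactionDef] = []
    genes: list[TemplateGene] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            kind = fields[0]
            try:
                if kind == "pathway" and len(fields) == 2:
                    name = fields[1]
                elif kind == "reaction" and len(fields) == 6:
                    reactions.append(
                        ReactionDef(
                            reaction_id=fields[1],
                            ec_numbers=tuple(x for x in fields[2].split(";") if x),
                            substrates=tuple(x for x in fields[3].split(";") if x),
                            products=tuple(x for x in fields[4].split(";") if x),
                            sub_pathway=fields[5],
                        )
                    )
                elif kind == "gene" and len(fields) == 6:
                    genes.append(
                        TemplateGene(
                            species=fields[1],
                            gene_id=fields[2],
                            function_label=fields[3],
                            ec_numbers=tuple(x for x in fields[4].split(";") if x),
                            clarity=fields[5],
                        )
                    )
                else:
                    raise FormatError(f"unrecognized row kind/arity {kind!r}")
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    try:
        return PathwayTemplate(name=name, reactions=tuple(reactions), template_genes=tuple(genes))
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_pathway_template(template: PathwayTemplate, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump(template.to_dict(), fh, indent=1)
            fh.write("\n")
        return
    with open(path, "w") as fh:
        fh.write(f"pathway\t{template.name}\n")
        for r in template.reactions:
            fh.write(
                "reaction\t{}\t{}\t{}\t{}\t{}\n".format(
                    r.reaction_id, ";".join(r.ec_numbers), ";".join(r.substrates),
                    ";".join(r.products), r.sub_pathway,
                )
            )
        for g in template.template_genes:
            fh.write(
                "gene\t{}\t{}\t{}\t{}\t{}\n".format(
                    g.species, g.gene_id, g.function_label, ";".join(g.ec_numbers), g.clarity,
                )
            )


# ---------------------------------------------------------------------------
# Expression matrix

def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Probe-by-condition expression matrix; first column is the probe id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate condition labels")
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate probe ids")
    values = df.to_numpy()
    if not ((values >= 0).all() and pd.notna(values).all()):
        raise FormatError(f"{path}: expression values must be finite and non-negative")
    return df


# ---------------------------------------------------------------------------
# Pathway graph export

def build_pathway_graph(pathway, overlay=None) -> nx.DiGraph:
    """Bipartite metabolite/reaction graph with annotation attributes.

    Reaction nodes carry the EC set, assigned protein ids, per-protein
    MS/CS/region, the gap flag, and (with an overlay) per-protein
    expression vectors as comma-joined decimal strings.
    """
    g = nx.DiGraph()
    if overlay is None:
        overlay = getattr(pathway, "overlay", None)
    for reaction in pathway.template.reactions:
        rnode = f"reaction:{reaction.reaction_id}"
        proteins = pathway.assignments.get(reaction.reaction_id, [])
        attrs = {
            "kind": "reaction",
            "ec": ";".join(reaction.ec_numbers),
            "sub_pathway": reaction.sub_pathway,
            "gap": reaction.reaction_id in pathway.gaps,
            "proteins": ";".join(p.query_id for p in proteins),
            "scores": ";".join(
                f"{p.query_id}:{p.ms:g}:{p.cs:g}:{p.region}" for p in proteins
            ),
        }
        if overlay is not None:
            attrs["conditions"] = ",".join(overlay.conditions)
            for p in proteins:
                gene = overlay.get(p.gene_id)
                if gene is not None:
                    attrs[f"expr_{p.query_id}"] = ",".join(repr(v) for v in gene.levels)
        g.add_node(rnode, **attrs)
        for met in reaction.substrates:
            g.add_node(met, kind="metabolite")
            g.add_edge(met, rnode)
        for met in reaction.products:
            g.add_node(met, kind="metabolite")
            g.add_edge(rnode, met)
    return g


def write_pathway_graph(
    pathway,
    path: str | Path,
    overlay=None,
    fmt: str = "graphml",
) -> None:
    g = build_pathway_graph(pathway, overlay)
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(g, str(path))
    elif fmt == "json":
        data = nx.node_link_data(g, edges="edges")
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown graph format {fmt!r} (use graphml or json)")
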