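"""Domain types and file formats: validation, round-trips, graph export."""

import json

import networkx as nx
import numpy as np
import pytest

from orthopath.annotate import AnnotationCandidate, EvidenceItem
from orthopath.formats import (
    build_pathway_graph,
    read_blast_tab,
    read_fasta,
    read_pathway_template,
    write_fasta,
    write_pathway_graph,
    write_pathway_template,
)
from orthopath.pathway import build_pathway
from orthopath.records import (
    FormatError,
    PathwayTemplate,
    ReactionDef,
    SequenceRecord,
    TemplateGene,
)
from orthopath.score import score_table

from conftest import random_protein


class TestSequenceRecord:
    def test_residues_are_uppercased(self):
        rec = SequenceRecord(id="g1", residues="acde", alphabet="protein")
        assert rec.residues == "ACDE"

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(id="g 1", residues="ACDE"),
            dict(id="g1", residues=""),
            dict(id="g1", residues="ACDEJ"),  # J is not an amino acid code
            dict(id="g1", residues="ACDE", alphabet="rna"),
            dict(id="g1", residues="MKVL", alphabet="nucleotide"),
        ],
    )
    def test_invalid_records_rejected(self, kwargs):
        with pytest.raises(FormatError):
            SequenceRecord(**kwargs)

    def test_gene_transcript_convention(self):
        rec = SequenceRecord(id="001042_001043", residues="MK")
        assert rec.gene_id == "001042"
        assert rec.transcript_id == "001043"
        unresolved = SequenceRecord(id="003884_xxxxxx", residues="MK")
        assert unresolved.gene_id == "003884"
        assert unresolved.transcript_id is None
        opaque = SequenceRecord(id="AT1G01010.1", residues="MK")
        assert opaque.gene_id == "AT1G01010.1"


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.faa"
        p.write_text(">g1\nacde\n")
        recs = read_fasta(p, "protein")
        assert len(recs) == 1 and recs[0].id == "g1" and recs[0].residues == "ACDE"

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "a.faa"
        p.write_text(">a\nMK\n>a\nML\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_fasta(p, "protein")

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "a.faa"
        p.write_text("")
        with pytest.raises(FormatError):
            read_fasta(p, "protein")

    def test_illegal_residue_names_record(self, tmp_path):
        p = tmp_path / "a.faa"
        p.write_text(">ok\nMK\n>bad\nM1K\n")
        with pytest.raises(FormatError, match="bad"):
            read_fasta(p, "protein")

    def test_round_trip_preserves_content(self, tmp_path):
        rng = np.random.default_rng(42)
        records = [
            random_protein(rng, int(rng.integers(1, 200)), f"rec{i:03d}")
            for i in range(100)
        ]
        p = tmp_path / "r.faa"
        write_fasta(records, p)
        back = read_fasta(p, "protein")
        assert [(r.id, r.residues) for r in back] == [
            (r.id, r.residues) for r in records
        ]


class TestBlastTab:
    LINE = "q1\ts1\t85.0\t200\t30\t0\t1\t200\t1\t200\t1e-80\t350"

    def test_full_span_hit(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(self.LINE + "\n")
        (hit,) = read_blast_tab(p, {"q1": 200})
        assert hit.pident == 85.0 and hit.qcov == 100.0 and hit.evalue == 1e-80

    def test_partial_span_coverage(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("q1\ts1\t85.0\t100\t15\t0\t51\t150\t1\t100\t1e-40\t180\n")
        (hit,) = read_blast_tab(p, {"q1": 200})
        assert hit.qcov == 50.0

    def test_wrong_column_count_reports_line(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("\t".join(self.LINE.split("\t")[:11]) + "\n")
        with pytest.raises(FormatError, match=":1"):
            read_blast_tab(p, {"q1": 200})

    def test_unknown_query_is_lookup_error(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(self.LINE + "\n")
        with pytest.raises(LookupError):
            read_blast_tab(p, {"other": 200})


def toy_template():
    return PathwayTemplate(
        name="toy",
        reactions=(
            ReactionDef("R1", ("2.4.1.13",), ("sucrose",), ("fructose",), "sucrose_synthesis"),
            ReactionDef("R2", ("2.7.7.27",), ("G1P",), ("ADPG",), "starch_synthesis"),
            ReactionDef("R3", ("4.1.1.39",), ("RuBP",), ("3PGA",), "calvin_cycle"),
        ),
        template_genes=(
            TemplateGene("arabidopsis", "AT1", "sucrose synthase", ("2.4.1.13",), "clear"),
            TemplateGene("rice", "OS1", "AGPase putative", ("2.7.7.27",), "unclear"),
        ),
    )


class TestPathwayTemplateIO:
    def test_toy_file_preserves_labels(self, tmp_path):
        p = tmp_path / "t.json"
        write_pathway_template(toy_template(), p)
        back = read_pathway_template(p)
        assert [r.sub_pathway for r in back.reactions] == [
            "sucrose_synthesis", "starch_synthesis", "calvin_cycle",
        ]

    def test_malformed_ec_rejected(self):
        with pytest.raises(FormatError, match="EC"):
            TemplateGene("sp", "g", "f", ("9.9.9",))
        with pytest.raises(FormatError):
            ReactionDef("R1", ("9.9.9",))

    def test_reaction_without_ec_rejected(self):
        with pytest.raises(FormatError):
            ReactionDef("R1", ())

    @pytest.mark.parametrize("suffix", ["json", "tsv"])
    def test_round_trip_equality(self, tmp_path, suffix):
        rng = np.random.default_rng(9)
        reactions = tuple(
            ReactionDef(
                f"R{i}", (f"1.2.3.{i}",), (f"M{i}",), (f"M{i+1}",),
                ("calvin_cycle", "sucrose_synthesis", "starch_synthesis", "other")[i % 4],
            )
            for i in range(20)
        )
        genes = tuple(
            TemplateGene(
                f"sp{i % 3}", f"g{i}", f"enzyme {i}", (f"1.2.3.{i % 20}",),
                "unclear" if i % 4 == 0 else "clear",
            )
            for i in range(12)
        )
        template = PathwayTemplate("rt", reactions, genes)
        p = tmp_path / f"t.{suffix}"
        write_pathway_template(template, p)
        assert read_pathway_template(p) == template

    def test_duplicate_reaction_ids_rejected(self):
        r = ReactionDef("R1", ("1.1.1.1",))
        with pytest.raises(FormatError, match="duplicate"):
            PathwayTemplate("x", (r, r))


def _annotated(template, ec, query_id="000001_000001"):
    gene = next(g for g in template.template_genes if ec in g.ec_numbers)
    ev = EvidenceItem(
        template_species=gene.species, template_gene=gene, hit_kind="rbh",
        H=1.0, F=gene.clarity_weight,
    )
    cand = AnnotationCandidate(
        query_id=query_id, function_label=gene.function_label,
        ec_numbers=(ec,), evidence=(ev,),
    )
    annotated, _ = score_table([cand])
    return annotated


class TestGraphExport:
    def test_single_reaction_graph_shape(self):
        template = toy_template()
        pw = build_pathway(template, _annotated(template, "2.4.1.13"))
        g = build_pathway_graph(pw)
        # R1: substrate + product + reaction node, 2 edges
        assert g.nodes["reaction:R1"]["gap"] is False
        assert set(g.predecessors("reaction:R1")) == {"sucrose"}
        assert set(g.successors("reaction:R1")) == {"fructose"}

    def test_gap_reaction_flagged(self):
        template = toy_template()
        pw = build_pathway(template, _annotated(template, "2.4.1.13"))
        g = build_pathway_graph(pw)
        assert g.nodes["reaction:R2"]["gap"] is True
        assert g.nodes["reaction:R2"]["proteins"] == ""

    @pytest.mark.parametrize("fmt", ["graphml", "json"])
    def test_export_parses_back_with_same_counts(self, tmp_path, fmt):
        template = toy_template()
        pw = build_pathway(template, _annotated(template, "2.4.1.13"))
        path = tmp_path / f"g.{fmt}"
        write_pathway_graph(pw, path, fmt=fmt)
        if fmt == "graphml":
            back = nx.read_graphml(path)
        else:
            with open(path) as fh:
                back = nx.node_link_graph(json.load(fh), edges="edges")
        g = build_pathway_graph(pw)
        assert back.number_of_nodes() == g.number_of_nodes()
        assert back.number_of_edges() == g.number_of_edges()

    def test_unknown_format_rejected(self, tmp_path):
        template = toy_template()
        pw = build_pathway(template, [])
        with pytest.raises(ValueError):
            write_pathway_graph(pw, tmp_path / "g.xml", fmt="dot")
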