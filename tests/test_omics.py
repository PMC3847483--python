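"""Probe mapping, fold-change filtering, and expression overlay export."""

import numpy as np
import pandas as pd
import pytest

from orthopath.formats import build_pathway_graph, write_pathway_graph
from orthopath.omics import attach_overlay, fold_change_filter, map_probes
from orthopath.pathway import build_pathway
from orthopath.records import PathwayTemplate, ReactionDef, SequenceRecord

from test_pathway import TEMPLATE, make_annotation

BASES = "ACGT"


def random_nt(rng, length, rid):
    idx = rng.integers(0, 4, size=length)
    return SequenceRecord(
        id=rid, residues="".join(BASES[i] for i in idx), alphabet="nucleotide"
    )


class TestMapProbes:
    def test_exact_substring_probe_maps(self):
        rng = np.random.default_rng(21)
        gene = random_nt(rng, 600, "000001_000001")
        probe = SequenceRecord(id="p1", residues=gene.residues[100:160], alphabet="nucleotide")
        mapping = map_probes([gene], [probe])
        assert mapping == {"000001": ["p1"]}

    def test_random_probe_does_not_map(self):
        rng = np.random.default_rng(22)
        gene = random_nt(rng, 600, "g1")
        decoy = random_nt(rng, 60, "p_decoy")
        assert map_probes([gene], [decoy]) == {}

    def test_probe_may_represent_multiple_genes(self):
        rng = np.random.default_rng(23)
        g1 = random_nt(rng, 600, "g1")
        g2 = SequenceRecord(id="g2", residues=g1.residues, alphabet="nucleotide")
        probe = SequenceRecord(id="p1", residues=g1.residues[10:70], alphabet="nucleotide")
        mapping = map_probes([g1, g2], [probe])
        assert mapping == {"g1": ["p1"], "g2": ["p1"]}

    def test_protein_input_rejected(self):
        prot = SequenceRecord(id="p", residues="MKVL", alphabet="protein")
        with pytest.raises(ValueError):
            map_probes([prot], [prot])

    def test_tightening_thresholds_never_adds_probes(self):
        rng = np.random.default_rng(24)
        genes = [random_nt(rng, 400, f"g{i}") for i in range(5)]
        probes = []
        for i, g in enumerate(genes):
            sub = list(g.residues[50:110])
            for pos in (10, 25, 40)[: i % 4]:  # 0..3 planted mismatches
                sub[pos] = next(b for b in BASES if b != sub[pos])
            probes.append(
                SequenceRecord(id=f"p{i}", residues="".join(sub), alphabet="nucleotide")
            )
        loose = map_probes(genes, probes, min_pident=90.0)
        tight = map_probes(genes, probes, min_pident=97.0)
        for gene_id, plist in tight.items():
            assert set(plist) <= set(loose.get(gene_id, []))


class TestFoldChangeFilter:
    def test_three_fold_gene_passes(self):
        table = pd.DataFrame(
            {"fibrous": [10.0], "developing": [10.0], "mature": [30.0]}, index=["p1"]
        )
        overlay = fold_change_filter(table, {"g1": ["p1"]})
        assert "g1" in overlay.genes
        assert overlay.genes["g1"].fold_ratio == pytest.approx(3.0)

    def test_one_point_five_fold_gene_is_excluded(self):
        table = pd.DataFrame(
            {"fibrous": [10.0], "developing": [12.0], "mature": [15.0]}, index=["p1"]
        )
        overlay = fold_change_filter(table, {"g1": ["p1"]})
        assert "g1" not in overlay.genes and "g1" in overlay.excluded

    def test_no_overlay_gene_fails_the_filter(self):
        rng = np.random.default_rng(25)
        table = pd.DataFrame(
            rng.uniform(1, 50, size=(30, 3)),
            columns=["fibrous", "developing", "mature"],
            index=[f"p{i}" for i in range(30)],
        )
        mapping = {f"g{i}": [f"p{i}"] for i in range(30)}
        overlay = fold_change_filter(table, mapping)
        for gene in overlay.genes.values():
            assert max(gene.levels) / max(min(gene.levels), 1.0) >= 2.0

    def test_mean_over_probes_is_order_invariant(self):
        table = pd.DataFrame(
            {"fibrous": [10.0, 20.0], "developing": [10.0, 30.0], "mature": [40.0, 80.0]},
            index=["p1", "p2"],
        )
        a = fold_change_filter(table, {"g1": ["p1", "p2"]})
        b = fold_change_filter(table, {"g1": ["p2", "p1"]})
        assert a.genes["g1"].levels == b.genes["g1"].levels == (15.0, 20.0, 60.0)

    def test_gene_without_expression_data_is_warned_and_dropped(self):
        table = pd.DataFrame(
            {"fibrous": [10.0], "developing": [10.0], "mature": [30.0]}, index=["p1"]
        )
        with pytest.warns(UserWarning):
            overlay = fold_change_filter(table, {"g1": ["p1"], "g2": ["p_missing"]})
        assert "g2" not in overlay.genes and "g2" not in overlay.excluded

    def test_planted_patterns_recovered(self, pipeline_result):
        result, manifest, _ = pipeline_result
        overlay = result.pathway.overlay
        assert sorted(overlay.genes) == manifest.expected_filter_passing_genes
        for gene in overlay.genes.values():
            assert gene.levels[0] < gene.levels[1] < gene.levels[2]


class TestAttachOverlay:
    def _pathway_with_overlay(self):
        ann = make_annotation("000001_000001", ["2.4.1.13"])
        pw = build_pathway(TEMPLATE, [ann])
        table = pd.DataFrame(
            {"fibrous": [10.0], "developing": [20.0], "mature": [41.5]}, index=["p1"]
        )
        overlay = fold_change_filter(table, {"000001": ["p1"]})
        return attach_overlay(pw, overlay), overlay

    def test_reaction_node_carries_condition_vector(self):
        pw, overlay = self._pathway_with_overlay()
        g = build_pathway_graph(pw)
        assert g.nodes["reaction:R1"]["expr_000001_000001"] == "10.0,20.0,41.5"
        assert g.nodes["reaction:R1"]["conditions"] == "fibrous,developing,mature"

    def test_non_passing_genes_absent_from_nodes(self):
        ann = make_annotation("000002_000002", ["2.7.7.27"])
        pw = build_pathway(TEMPLATE, [ann])
        table = pd.DataFrame(
            {"fibrous": [10.0], "developing": [11.0], "mature": [12.0]}, index=["p1"]
        )
        overlay = fold_change_filter(table, {"000002": ["p1"]})
        g = build_pathway_graph(attach_overlay(pw, overlay))
        assert "expr_000002_000002" not in g.nodes["reaction:R2"]

    def test_graphml_round_trip_preserves_decimal_strings(self, tmp_path):
        import networkx as nx

        pw, _ = self._pathway_with_overlay()
        path = tmp_path / "g.graphml"
        write_pathway_graph(pw, path, fmt="graphml")
        back = nx.read_graphml(path)
        assert back.nodes["reaction:R1"]["expr_000001_000001"] == "10.0,20.0,41.5"
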