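"""Reciprocal-best-hit detection, filtering and function assignment."""

import json

import numpy as np
import pytest

from orthopath.align import AlignmentHit, ScoringScheme
from orthopath.annotate import (
    FilterConfig,
    apply_filters,
    assign_functions,
    find_rbh,
)
from orthopath.records import PathwayTemplate, ReactionDef, SequenceRecord, TemplateGene
from orthopath.simulate import mutate_sequence

from conftest import random_protein

CFG = FilterConfig()


def hit(evalue=1e-20, pident=90.0, qcov=95.0, q="q", s="s", bits=100.0):
    return AlignmentHit(
        query_id=q, subject_id=s, bitscore=bits, evalue=evalue, pident=pident, qcov=qcov
    )


class TestApplyFilters:
    def test_boundary_values_are_kept(self):
        kept = apply_filters([hit(evalue=1e-10, pident=60.0, qcov=80.0)], CFG)
        assert len(kept) == 1

    @pytest.mark.parametrize(
        "bad",
        [
            dict(pident=59.9),
            dict(qcov=79.9),
            dict(evalue=1.0000001e-10),
        ],
    )
    def test_just_below_threshold_removed(self, bad):
        assert apply_filters([hit(**bad)], CFG) == []

    def test_order_preserved(self):
        hits = [hit(s=f"s{i}", pident=60.0 + i) for i in range(5)]
        assert apply_filters(hits, CFG) == hits

    def test_kept_set_shrinks_as_thresholds_tighten(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            hits = [
                hit(
                    evalue=10.0 ** -rng.uniform(0, 30),
                    pident=rng.uniform(0, 100),
                    qcov=rng.uniform(1, 100),
                    s=f"s{j}",
                )
                for j in range(10)
            ]
            base = FilterConfig(
                max_evalue=10.0 ** -rng.uniform(0, 20),
                min_pident=rng.uniform(0, 90),
                min_qcov=rng.uniform(0, 90),
            )
            tighter = FilterConfig(
                max_evalue=base.max_evalue / 10 ** rng.uniform(0, 3),
                min_pident=min(100, base.min_pident + rng.uniform(0, 10)),
                min_qcov=min(100, base.min_qcov + rng.uniform(0, 10)),
            )
            kept = apply_filters(hits, base)
            assert len(apply_filters(hits, tighter)) <= len(kept)
            assert set(h.subject_id for h in apply_filters(kept, tighter)) <= set(
                h.subject_id for h in kept
            )


def _family(rng, length=120):
    ancestor = random_protein(rng, length, "anc")
    return ancestor


class TestFindRbh:
    def test_identical_pair_is_rbh(self):
        rng = np.random.default_rng(1)
        anc = _family(rng)
        gene_rec = SequenceRecord(id="tg1", residues=anc.residues, species="sp")
        query_rec = SequenceRecord(id="q1", residues=anc.residues, species="query")
        other = random_protein(rng, 100, "bg1", species="sp")
        gene = TemplateGene("sp", "tg1", "enzyme x", ("1.1.1.1",), "clear")
        result = find_rbh(gene, [gene_rec, other], [query_rec], CFG)
        assert result is not None
        qid, ev = result
        assert qid == "q1" and ev.H == 1.0 and ev.hit_kind == "rbh"

    def test_missing_gene_raises_lookup_error(self):
        gene = TemplateGene("sp", "absent", "enzyme x", ("1.1.1.1",))
        rng = np.random.default_rng(2)
        with pytest.raises(LookupError):
            find_rbh(gene, [random_protein(rng, 80, "tg", species="sp")],
                     [random_protein(rng, 80, "q")], CFG)

    def test_planted_reverse_competitor_breaks_rbh(self):
        # the second pass finds a strictly better template partner, so the
        # forward best hit is not reciprocal
        rng = np.random.default_rng(3)
        anc = _family(rng)
        t = mutate_sequence(anc, 0.80, rng, "t_distant", species="sp")
        c = mutate_sequence(anc, 0.95, rng, "c_query", species="query")
        competitor = SequenceRecord(id="t_close", residues=c.residues, species="sp")
        gene = TemplateGene("sp", "t_distant", "enzyme x", ("1.1.1.1",))
        assert find_rbh(gene, [t, competitor], [c], CFG) is None
        # removing the competitor restores reciprocity (double argmax check)
        assert find_rbh(gene, [t], [c], CFG)[0] == "c_query"

    def test_rbh_relation_is_symmetric(self):
        rng = np.random.default_rng(4)
        n = 12
        ancestors = [_family(rng, 90) for _ in range(n)]
        side_a = [mutate_sequence(a, 0.9, rng, f"a{i}", species="A") for i, a in enumerate(ancestors)]
        side_b = [mutate_sequence(a, 0.9, rng, f"b{i}", species="B") for i, a in enumerate(ancestors)]
        for i in range(n):
            ga = TemplateGene("A", f"a{i}", "fx", ("1.1.1.1",))
            gb = TemplateGene("B", f"b{i}", "fx", ("1.1.1.1",))
            from_a = find_rbh(ga, side_a, side_b, CFG)
            from_b = find_rbh(gb, side_b, side_a, CFG)
            if from_a is not None and from_a[0] == f"b{i}":
                assert from_b is not None and from_b[0] == f"a{i}"
            if from_b is not None and from_b[0] == f"a{i}":
                assert from_a is not None and from_a[0] == f"b{i}"


def _single_species_setup(rng):
    anc = _family(rng, 150)
    gene_rec = mutate_sequence(anc, 0.95, rng, "tg1", species="sp")
    query_rec = mutate_sequence(anc, 0.92, rng, "q1", species="query")
    template = PathwayTemplate(
        name="t",
        reactions=(ReactionDef("R1", ("1.1.1.1",)),),
        template_genes=(TemplateGene("sp", "tg1", "enzyme x", ("1.1.1.1",), "clear"),),
    )
    return template, gene_rec, query_rec


class TestAssignFunctions:
    def test_single_rbh_yields_single_candidate(self):
        rng = np.random.default_rng(5)
        template, gene_rec, query_rec = _single_species_setup(rng)
        cands = assign_functions(template, {"sp": [gene_rec]}, [query_rec], CFG)
        assert len(cands) == 1
        (c,) = cands
        assert c.query_id == "q1" and c.n_m == 1
        assert c.evidence[0].H == 1.0 and c.evidence[0].F == 1.0

    def test_secondary_hit_confirmed_only_on_identical_function(self):
        rng = np.random.default_rng(6)
        anc = _family(rng, 150)
        g1 = mutate_sequence(anc, 0.95, rng, "g1", species="sp")
        # same-family template gene under a different label
        g2 = mutate_sequence(anc, 0.82, rng, "g2", species="sp")
        q1 = mutate_sequence(anc, 0.93, rng, "q1", species="query")
        template = PathwayTemplate(
            name="t",
            reactions=(ReactionDef("R1", ("1.1.1.1",)), ReactionDef("R2", ("2.2.2.2",))),
            template_genes=(
                TemplateGene("sp", "g1", "function alpha", ("1.1.1.1",)),
                TemplateGene("sp", "g2", "function beta", ("2.2.2.2",)),
            ),
        )
        cands = assign_functions(template, {"sp": [g1, g2]}, [q1], CFG)
        labels = {c.function_label for c in cands}
        # q1's reverse best is g1 (function alpha): g2's forward hit on q1
        # must not create a "function beta" annotation
        assert labels == {"function alpha"}

    def test_evidence_counts_species_with_planted_orthologs(self):
        rng = np.random.default_rng(7)
        anc = _family(rng, 150)
        species = [f"sp{i}" for i in range(5)]
        proteomes = {}
        genes = []
        for i, sp in enumerate(species):
            background = random_protein(rng, 120, f"bg_{sp}", species=sp)
            if i < 3:  # orthologs planted in three of five species
                rec = mutate_sequence(anc, 0.9, rng, f"tg_{sp}", species=sp)
                proteomes[sp] = [rec, background]
                genes.append(TemplateGene(sp, f"tg_{sp}", "enzyme y", ("1.1.1.1",)))
            else:
                proteomes[sp] = [background]
        template = PathwayTemplate(
            name="t", reactions=(ReactionDef("R1", ("1.1.1.1",)),),
            template_genes=tuple(genes),
        )
        q = mutate_sequence(anc, 0.9, rng, "q1", species="query")
        cands = assign_functions(template, proteomes, [q], CFG)
        assert len(cands) == 1 and cands[0].n_m == 3

    def test_every_evidence_hit_passes_filters(self):
        rng = np.random.default_rng(8)
        template, gene_rec, query_rec = _single_species_setup(rng)
        paralog = mutate_sequence(query_rec, 0.97, rng, "q2", species="query")
        cands = assign_functions(template, {"sp": [gene_rec]}, [query_rec, paralog], CFG)
        assert len(cands) == 2
        for c in cands:
            for e in c.evidence:
                assert CFG.passes(e.forward_hit)
                assert CFG.passes(e.reverse_hit)

    def test_byte_identical_output_on_rerun(self):
        rng1 = np.random.default_rng(9)
        rng2 = np.random.default_rng(9)
        out = []
        for rng in (rng1, rng2):
            template, gene_rec, query_rec = _single_species_setup(rng)
            cands = assign_functions(template, {"sp": [gene_rec]}, [query_rec], CFG)
            out.append(json.dumps([c.to_dict() for c in cands], sort_keys=True))
        assert out[0] == out[1]
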