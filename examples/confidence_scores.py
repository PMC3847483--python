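"""Match score (MS), conservation score (CS) and confidence regions.

Each template species supporting an annotation contributes a weight
H*F: H is 1 for a reciprocal best hit and 0.5 for a second-pass-confirmed
hit; F is 1 for a clearly annotated template gene and 0.5 otherwise.
MS averages the weights over the N_m supporting species (alignment
quality); CS divides by the total template count N_t (cross-species
conservation).  Regions: A = weak match, B = strong match but weakly
conserved, C = strong match and widely conserved.
"""

from orthopath.annotate import EvidenceItem
from orthopath.records import TemplateGene
from orthopath.score import ScoreConfig, classify_region, compute_cs, compute_ms


def make_profile(hf_pairs):
    items = []
    for i, (h, f) in enumerate(hf_pairs):
        gene = TemplateGene(
            f"species_{i}", f"g{i}", "sucrose synthase", ("2.4.1.13",),
            "clear" if f == 1.0 else "unclear",
        )
        items.append(EvidenceItem(
            template_species=f"species_{i}", template_gene=gene,
            hit_kind="rbh" if h == 1.0 else "secondary_confirmed", H=h, F=f,
        ))
    return items


config = ScoreConfig(n_templates=5)
profiles = {
    "RBH + clear in all 5 species": [(1.0, 1.0)] * 5,
    "RBH + clear in 1 species only": [(1.0, 1.0)],
    "secondary hits, 3 species": [(0.5, 1.0)] * 3,
    "mixed evidence, 4 species": [(1.0, 1.0), (1.0, 0.5), (0.5, 1.0), (0.5, 0.5)],
}

print(f"{'profile':<32} {'N_m':>3} {'MS':>6} {'CS':>6}  region")
for name, pairs in profiles.items():
    ev = make_profile(pairs)
    ms, cs = compute_ms(ev), compute_cs(ev, config)
    print(f"{name:<32} {len(ev):>3} {ms:>6.2f} {cs:>6.2f}  {classify_region(ms, cs, config)}")
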