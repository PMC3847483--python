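# Methods

## Annotation model

`orthopath` treats functional annotation of an unannotated ("query")
proteome as an evidence-aggregation problem over several well-annotated
template species.  The unit of evidence is one template species'
support for one (query protein, function) pair, obtained by a two-pass
local-alignment protocol:

1. *First pass.*  The template gene is aligned against every query
   protein.  Hits are kept only if E-value ≤ `max_evalue` (default
   10⁻¹⁰), percent identity ≥ `min_pident` (60) and query coverage ≥
   `min_qcov` (80).  All three comparisons are inclusive: a hit exactly
   at a printed threshold is retained.  Identity is measured over
   alignment columns of the local alignment; coverage over the query's
   full length.
2. *Second pass.*  The best filtered hit is aligned back against the
   template proteome (same filters).  If its best hit is the original
   template gene, the pair is a reciprocal best hit (H = 1).  Any other
   filtered first-pass hit is retained with H = 0.5 only if its own
   second-pass best hit carries an identical function label (equality
   after case-folding and whitespace collapsing).  The reverse pass
   enforces the same three thresholds — a deliberate choice where the
   protocol's description is silent.

Ties in "best hit" are broken by bitscore (descending), then E-value
(ascending), then subject id (ascending), making every stage
deterministic.  Per (query, function, species) only the strongest
evidence item is kept (larger H, then larger forward bitscore), so the
species count N_m counts species, not template gene copies.  A query
protein may hold several distinct functions; scores are computed per
(protein, function) pair, since evidence lists are function-specific.

## Confidence scores

With evidence weights H·F (F = 1 for clearly annotated template genes,
0.5 for tentative ones, e.g. "putative" annotations):

* MS = Σ H·F / N_m — mean evidence quality over supporting species;
* CS = Σ H·F / N_t — the same mass spread over all N_t templates
  employed (default 5).

Each term H·F is at least 0.25, so annotated proteins have strictly
positive scores; a protein with no evidence is *unannotated*, never a
score-0 row.  CS ≤ MS always, with equality iff N_m = N_t; the
implementation asserts CS = MS·N_m/N_t to one ulp.

The A/B/C confidence regions of the MS–CS plane are qualitative in
origin; the defaults MS ≥ 0.7 ("well matched") and CS ≥ 0.5 ("widely
conserved": with N_t = 5 this requires strong evidence in at least
three species) preserve that geometry and are CLI-configurable
(`--ms-threshold`, `--cs-threshold`).

## Alignment engine

Smith–Waterman with affine gaps is delegated to Biopython's
`PairwiseAligner` (Gotoh local mode).  Conventions owned by this
package: a gap of length k costs `gap_open + k·gap_extend` (protein
defaults 11/1, nucleotide 5/2); BLOSUM62 for proteins and +5/−4 for
nucleotides, with the ambiguity codes X and N scoring 0 against
everything and never counted as identities; a zero-score optimum is
reported as "no hit".  E-values use the Karlin–Altschul form
E = K·m·n·e^(−λS) with λ = 0.267, K = 0.041 for the protein parameter
set (standard published gapped-BLOSUM62 constants) and λ = 0.19,
K = 0.1 for +5/−4 (λ solved from the uniform-composition identity
Σ pᵢpⱼe^(λsᵢⱼ) = 1; K an order-of-magnitude constant).  No
composition-based adjustment is attempted; faithful reproduction of any
particular BLAST release's E-values is explicitly not promised, and
real BLAST tabular output can be substituted via `read_blast_tab`.
The traceback reported is the aligner's first optimal alignment, which
is deterministic for fixed inputs.

The test suite checks the engine against an independent brute-force
oracle that enumerates every local alignment path on short sequences;
agreement is exact.

## Pathway assembly and validation

Annotations attach to every reaction whose EC set intersects theirs
(one shared EC suffices); EC numbers, not free-text labels, are the
join key.  Reactions with no attached protein are metabolic gaps; gap
detection is pure bookkeeping, no gap-filling is attempted.  Statistics
report, per sub-pathway, reaction/gap counts and proteins per covered
reaction, and per species the template-gene count versus the number of
distinct query proteins that species' evidence reached.

Known-gene validation aligns a curated protein set against the
annotated proteins; a match requires E ≤ 10⁻¹⁰ and identity ≥ 90
(inclusive), is recorded at the protein level, and sets the
`validated` flag consumed by the MS–CS scatter.  Nucleotide known genes
must be translated upstream.

## Transcriptome overlay

Probes (as queries) map to transcripts at E ≤ 10⁻¹⁰ and identity ≥ 95;
a probe may represent several genes.  Gene-level expression is the
arithmetic mean over mapped probes (probe count recorded).  The
two-fold criterion is operationalized symmetrically as
max/min ≥ `fold` across all conditions, with the minimum clamped at a
floor of 1 signal unit to avoid division by zero; no reference
condition is singled out.  Only passing genes are attached to reaction
nodes; vectors survive GraphML round-trips bit-exactly as decimal
strings.  Microarray normalization is out of scope — the pipeline
consumes already-processed values.

## Synthetic data

The generator emulates the five-template study design.  Per family an
ancestral protein (uniform composition, length 200–400) is mutated
independently into each template ortholog and the query ortholog at an
identity drawn from 80–95 % (integer percent grid).  Mutation is
substitution-only with exact realized identity
(round(target·L)/L matching positions) and matrix-plausible
replacements (score ≥ 0 against the original where possible), so the
true pairwise identity between any two family members is bounded below
by 1 − d₁ − d₂ ≥ 60 % — the filter boundary — and mismatch columns
rarely score negatively, keeping optimal local alignments full-span.
Decoys are mutated to 25–30 % identity: far below the identity filter
yet still alignable, so they exercise the identity/coverage criteria
rather than the E-value alone.  Every even-indexed family is present in
all species; odd-indexed families occupy a random subset of 2–4
species, varying N_m.

Paralogs are modelled as *recent duplicates* (98 % identity) of the
query ortholog, planted only in fully conserved families whose
identities are drawn from 85–95 %: the duplicate then clears the
filters in every template species with margin, and — because its extra
substitutions are placed at ancestor-conserved sites and are forbidden
from matching the ortholog's or any template's residue — it can never
outscore the true ortholog, so it deterministically takes the
second-pass H = 0.5 route.  Unclear-function ("putative") labels are
assigned family-wide (20 % of families) so that a family's evidence
shares one label and N_m counts species.

Transcripts are uniform random synonymous back-translations; probes are
exact or one-mismatch 60-mers of ortholog transcripts plus random
decoy probes.  Synonymous codon randomization keeps probe identity to
the paralog's transcript far below the 95 % mapping threshold, so the
probe→gene map equals its manifest by construction.  Expression
patterns are planted exactly: starch-synthesis families rise
monotonically across fibrous → developing → mature root conditions
(12:30:70, ≥ 2-fold), all other families stay flat (20:24:22,
< 2-fold).

What passing tests show — and do not show.  Recovery of every manifest
expectation demonstrates the pipeline's logic (filtering, reciprocity,
evidence bookkeeping, gap detection, fold filtering) under clean
conditions: substitution-only evolution, no indels, no domain shuffling,
no shared multi-domain architecture, no array batch effects.  Real
proteomes violate all of these, so perfect precision/recall on the
synthetic study is a correctness check, not a performance claim.

## Numerical and design choices

* Raw alignment scores are integers; E-values/bitscores are computed
  from the rounded score, so imported BLAST hits and internal hits sort
  identically.
* An E-value prefilter inside the annotation hit cache skips traceback
  for pairs that cannot pass the downstream inclusive E-value filter;
  it is exactly semantics-preserving and only a speed optimization.
* Determinism: all generator randomness flows from one integer-seeded
  PCG64 stream; identity targets are drawn on an integer percent grid;
  outputs (JSON/TSV/GraphML) are written with sorted keys and fixed
  column orders, so reruns are byte-identical.
* Degenerate inputs: empty proteomes, empty evidence lists, empty known
  sets and reactions without EC numbers are rejected or warned about
  explicitly rather than silently producing zero scores.
* Problem sizes in the tests (30 families for the full-recovery run,
  20×20 proteomes for the RBH oracle, length ≤ 6 pairs for the
  alignment oracle) are chosen so each oracle remains exhaustive or
  exactly checkable at desk scale.

## Known limitations

* The aligner is exact but O(mn) per pair with no heuristic seeding —
  suitable for pathway-scale template sets, not genome-scale
  all-vs-all surveys; for those, import BLAST tabular hits instead.
* Karlin–Altschul constants are fixed per scoring scheme, not estimated
  from composition; absolute E-values differ from BLAST's, though the
  inclusive-threshold semantics are unaffected for well-separated data.
* Conserved-domain (motif) validation against external services is out
  of scope; only the known-gene validation route is implemented.
* Gene-level rollup of isoforms via the 12-digit gene/transcript id
  convention is a reporting convenience; annotation itself is at the
  protein-record level.
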