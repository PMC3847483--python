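"""Independent oracles used by the test suite.

The local-alignment oracle exhaustively explores every local alignment
path (start anywhere, extend by aligned pair / gap-in-query /
gap-in-subject, end on an aligned pair) with affine gap costs
open + k*extend, taking the running maximum.  No dynamic-programming
table is shared with the engine under test.
"""

from __future__ import annotations

from orthopath.align import ScoringScheme, local_align, substitution_score
from orthopath.records import SequenceRecord


def brute_force_local_score(q: str, s: str, scheme: ScoringScheme) -> float:
    """Maximum score over every local alignment; 0 if none is positive.

    Alignments with terminal gaps are dominated (gap costs are strictly
    positive), so enumerating paths that start and end with an aligned
    pair covers every maximizer.
    """
    op, ext = scheme.gap_open, scheme.gap_extend
    best = 0.0
    nq, ns = len(q), len(s)

    def extend(i: int, j: int, score: float, last: str) -> None:
        nonlocal best
        if last == "M" and score > best:
            best = score
        if i < nq and j < ns:
            extend(i + 1, j + 1, score + substitution_score(q[i], s[j], scheme), "M")
        if i < nq:
            extend(i + 1, j, score - (ext if last == "D" else op + ext), "D")
        if j < ns:
            extend(i, j + 1, score - (ext if last == "I" else op + ext), "I")

    for i in range(nq):
        for j in range(ns):
            extend(i + 1, j + 1, substitution_score(q[i], s[j], scheme), "M")
    return best


def brute_force_rbh_pairs(
    proteome_a: list[SequenceRecord],
    proteome_b: list[SequenceRecord],
    scheme: ScoringScheme,
    config,
) -> set[tuple[str, str]]:
    """Double-argmax reciprocal best hits via direct all-vs-all alignment.

    Best hit per query = max over filtered hits by (bitscore, -evalue,
    -subject_id) with the package's deterministic tie order.
    """
    db_a = sum(len(r) for r in proteome_a)
    db_b = sum(len(r) for r in proteome_b)

    def best_of(query, subjects, db):
        cands = []
        for rec in subjects:
            hit = local_align(query, rec, scheme, database_residues=db)
            if hit is not None and config.passes(hit):
                cands.append(hit)
        if not cands:
            return None
        return min(cands, key=lambda h: (-h.bitscore, h.evalue, h.subject_id))

    pairs = set()
    for a in proteome_a:
        fwd = best_of(a, proteome_b, db_b)
        if fwd is None:
            continue
        b = next(r for r in proteome_b if r.id == fwd.subject_id)
        rev = best_of(b, proteome_a, db_a)
        if rev is not None and rev.subject_id == a.id:
            pairs.add((a.id, b.id))
    return pairs
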