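"""Local alignment engine: Smith–Waterman affine-gap alignments with
percent identity, query coverage, and Karlin–Altschul E-values.

This stands in for an external BLASTp/BLASTn run so the pipeline is
self-contained; precomputed BLAST tabular hits can be substituted at the
annotation layer.  The dynamic programming itself is delegated to
Biopython's PairwiseAligner (Gotoh local mode); this module owns the
scoring conventions and hit statistics.

Conventions
-----------
* A gap of length k costs ``gap_open + k * gap_extend``.
* 'X' (protein) and 'N' (nucleotide) score 0 against everything and are
  never counted as identities.
* An optimal local score of 0 is reported as "no hit" (``None``), not as
  a degenerate alignment.
* E = K * m * n * exp(-lambda * S); bitscore = (lambda * S - ln K)/ln 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .records import SequenceRecord

AMBIGUOUS = {"protein": "X", "nucleotide": "N"}


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and Karlin–Altschul constants.

    Defaults follow common BLAST practice: BLOSUM62 with gap open 11 /
    extend 1 for proteins (lambda=0.267, K=0.041, the standard gapped
    constants for that parameter set), and match +5 / mismatch -4 with
    open 5 / extend 2 for nucleotides.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    alphabet: str = "protein"

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ValueError("require gap_open >= gap_extend >= 1")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin–Altschul constants must be positive")

    @classmethod
    def protein_default(cls) -> "ScoringScheme":
        return cls()

    @classmethod
    def nucleotide_default(cls) -> "ScoringScheme":
        # lambda solved from sum p_i p_j exp(lambda s_ij) = 1 at uniform
        # base composition for +5/-4; K is an order-of-magnitude constant.
        return cls(
            matrix_name="NUC+5/-4",
            gap_open=5,
            gap_extend=2,
            karlin_lambda=0.19,
            karlin_k=0.1,
            alphabet="nucleotide",
        )

    @classmethod
    def for_alphabet(cls, alphabet: str) -> "ScoringScheme":
        return cls.protein_default() if alphabet == "protein" else cls.nucleotide_default()


@dataclass(frozen=True)
class AlignmentHit:
    """One scored local alignment (spans are 1-based, inclusive)."""

    query_id: str
    subject_id: str
    bitscore: float
    evalue: float
    pident: float
    qcov: float
    raw_score: int | None = None
    qstart: int = 0
    qend: int = 0
    sstart: int = 0
    send: int = 0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if not (0.0 <= self.pident <= 100.0):
            raise ValueError("pident must lie in [0, 100]")

    def to_dict(self) -> dict:
        return {
            "query_id": self.query_id,
            "subject_id": self.subject_id,
            "bitscore": self.bitscore,
            "evalue": self.evalue,
            "pident": self.pident,
            "qcov": self.qcov,
            "raw_score": self.raw_score,
            "qstart": self.qstart,
            "qend": self.qend,
            "sstart": self.sstart,
            "send": self.send,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AlignmentHit":
        return cls(**d)


@lru_cache(maxsize=8)
def _matrix(matrix_name: str) -> substitution_matrices.Array:
    if matrix_name == "NUC+5/-4":
        m = substitution_matrices.Array(alphabet="ACGTN", dims=2)
        for x in "ACGT":
            for y in "ACGT":
                m[x, y] = 5.0 if x == y else -4.0
        return m
    m = substitution_matrices.load(matrix_name).copy()
    # Ambiguity codes are scored 0 against everything.
    for amb in ("X", "N"):
        if amb in m.alphabet:
            for other in m.alphabet:
                m[amb, other] = 0.0
                m[other, amb] = 0.0
    return m


@lru_cache(maxsize=8)
def _aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _matrix(scheme.matrix_name)
    aligner.mode = "local"
    # Biopython charges open_gap_score for the first gapped column, so the
    # "open + k*extend" convention maps onto -(open+extend) / -extend.
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def substitution_score(a: str, b: str, scheme: ScoringScheme) -> float:
    return float(_matrix(scheme.matrix_name)[a, b])


def estimate_evalue(
    raw_score: float,
    query_length: int,
    database_residues: int,
    scheme: ScoringScheme,
) -> float:
    """Karlin–Altschul expected number of chance hits at this score."""
    if query_length <= 0 or database_residues <= 0:
        raise ValueError("query_length and database_residues must be positive")
    return (
        scheme.karlin_k
        * query_length
        * database_residues
        * math.exp(-scheme.karlin_lambda * raw_score)
    )


def bit_score(raw_score: float, scheme: ScoringScheme) -> float:
    return (scheme.karlin_lambda * raw_score - math.log(scheme.karlin_k)) / math.log(2)


def local_align(
    query: SequenceRecord,
    subject: SequenceRecord,
    scheme: ScoringScheme | None = None,
    database_residues: int | None = None,
) -> AlignmentHit | None:
    """Optimal local alignment of query vs subject, or None if no positive
    score exists.

    ``database_residues`` sets the search-space size n for the E-value;
    it defaults to the subject length (single-sequence database).
    """
    if scheme is None:
        scheme = ScoringScheme.for_alphabet(query.alphabet)
    if query.alphabet != subject.alphabet or query.alphabet != scheme.alphabet:
        raise ValueError(
            f"alphabet mismatch: query={query.alphabet}, subject={subject.alphabet}, "
            f"scheme={scheme.alphabet}"
        )
    if not query.residues or not subject.residues:
        raise ValueError("cannot align empty sequences")

    aligner = _aligner(scheme)
    alignments = aligner.align(query.residues, subject.residues)
    score = float(alignments.score) if alignments else 0.0
    if score <= 0:
        return None
    aln = alignments[0]  # deterministic first optimal traceback
    qblocks, sblocks = aln.aligned
    qstart0, qend0 = int(qblocks[0][0]), int(qblocks[-1][1])
    sstart0, send0 = int(sblocks[0][0]), int(sblocks[-1][1])

    ambiguous = AMBIGUOUS[scheme.alphabet]
    matches = 0
    aligned_len = 0
    for (qa, qb), (sa, sb) in zip(qblocks, sblocks):
        aligned_len += qb - qa
        for qres, sres in zip(query.residues[qa:qb], subject.residues[sa:sb]):
            if qres == sres and qres != ambiguous:
                matches += 1
    qspan = qend0 - qstart0
    sspan = send0 - sstart0
    columns = qspan + sspan - aligned_len  # aligned pairs + gapped columns
    pident = 100.0 * matches / columns
    qcov = 100.0 * qspan / len(query)
    n = database_residues if database_residues is not None else len(subject)
    raw = int(round(score))
    return AlignmentHit(
        query_id=query.id,
        subject_id=subject.id,
        raw_score=raw,
        bitscore=bit_score(raw, scheme),
        evalue=estimate_evalue(raw, len(query), n, scheme),
        pident=pident,
        qcov=qcov,
        qstart=qstart0 + 1,
        qend=qend0,
        sstart=sstart0 + 1,
        send=send0,
    )


def raw_local_score(
    query: SequenceRecord, subject: SequenceRecord, scheme: ScoringScheme
) -> float:
    """Optimal local score only (no traceback); cheaper than local_align."""
    return float(_aligner(scheme).score(query.residues, subject.residues))


def hit_sort_key(hit: AlignmentHit) -> tuple:
    """Deterministic hit ordering: bitscore desc, evalue asc, subject id asc."""
    return (-hit.bitscore, hit.evalue, hit.subject_id)


def best_hits(
    queries: Sequence[SequenceRecord] | Mapping[str, SequenceRecord],
    subjects: Sequence[SequenceRecord] | Mapping[str, SequenceRecord],
    scheme: ScoringScheme | None = None,
) -> dict[str, list[AlignmentHit]]:
    """All-vs-all local alignments, per query, deterministically sorted."""
    qrecs = list(queries.values()) if isinstance(queries, Mapping) else list(queries)
    srecs = list(subjects.values()) if isinstance(subjects, Mapping) else list(subjects)
    if not qrecs or not srecs:
        raise ValueError("proteomes must be non-empty")
    if scheme is None:
        scheme = ScoringScheme.for_alphabet(qrecs[0].alphabet)
    db_size = sum(len(s) for s in srecs)
    out: dict[str, list[AlignmentHit]] = {}
    for q in qrecs:
        hits = []
        for s in srecs:
            hit = local_align(q, s, scheme, database_residues=db_size)
            if hit is not None:
                hits.append(hit)
        hits.sort(key=hit_sort_key)
        out[q.id] = hits
    return out
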