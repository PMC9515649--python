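"""Pairwise protein alignment, percent identity and E-value estimation.

Global (Needleman-Wunsch) and local (Smith-Waterman) alignment with affine
gap penalties, used by the sheath phylogeny, the fusion-domain identity
reports and the effector similarity screen.  Dynamic programming is done by
:class:`Bio.Align.PairwiseAligner`; this module fixes the scoring
conventions and wraps the result in a small :class:`Alignment` record.

Scoring defaults follow BLASTP: BLOSUM62, gap open 11, gap extend 1 (a gap
of length k costs ``open + (k - 1) * extend``).  Bit scores use the
Karlin-Altschul transform with the standard gapped BLOSUM62 constants
(lambda = 0.267, K = 0.041), and E-values the BLAST formula
``E = m * n * 2**(-bits)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align as _bio_align
from Bio.Align import substitution_matrices

#: Karlin-Altschul constants for gapped BLOSUM62 (11/1), config-overridable.
KA_LAMBDA = 0.267
KA_K = 0.041

VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")

GAP = "-"


class AlignmentError(ValueError):
    """Raised for invalid alignment inputs (e.g. empty sequences)."""


class UndefinedIdentity(ValueError):
    """Raised when identity is requested for a zero-column alignment.

    Distinct from an identity of 0.0: an empty local alignment carries no
    evidence either way.
    """


@dataclass
class Alignment:
    """A scored pairwise alignment.

    ``aligned_query``/``aligned_subject`` are equal-length gapped strings
    (empty for an empty local alignment).  ``identity_fraction`` uses the
    alignment-columns convention (gapped columns count in the denominator);
    use :func:`percent_identity` for other conventions.
    """

    query_id: str
    subject_id: str
    aligned_query: str
    aligned_subject: str
    raw_score: float
    bit_score: float
    query_len: int
    subject_len: int
    query_start: int = 0
    query_end: int = 0
    subject_start: int = 0
    subject_end: int = 0

    @property
    def columns(self) -> int:
        return len(self.aligned_query)

    @property
    def matches(self) -> int:
        return sum(
            1
            for a, b in zip(self.aligned_query, self.aligned_subject)
            if a == b and a != GAP
        )

    @property
    def is_empty(self) -> bool:
        return self.columns == 0

    @property
    def identity_fraction(self) -> float:
        if self.is_empty:
            return 0.0
        return self.matches / self.columns

    @property
    def query_coverage(self) -> float:
        return (self.query_end - self.query_start) / self.query_len

    @property
    def subject_coverage(self) -> float:
        return (self.subject_end - self.subject_start) / self.subject_len


@lru_cache(maxsize=None)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@lru_cache(maxsize=None)
def _aligner(mode: str, matrix: str, gap_open: float, gap_extend: float):
    aligner = _bio_align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = _load_matrix(matrix)
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def _check_seq(seq: str, name: str) -> None:
    if not seq:
        raise AlignmentError(f"{name} sequence is empty")
    bad = set(seq) - VALID_AA
    if bad:
        raise AlignmentError(f"{name} contains non amino-acid letters: {sorted(bad)}")


def bit_score(raw_score: float, lam: float = KA_LAMBDA, K: float = KA_K) -> float:
    """Karlin-Altschul normalised score: ``(lambda*S - ln K) / ln 2``."""
    return (lam * raw_score - math.log(K)) / math.log(2)


def evalue(bits: float, query_len: int, db_residues: int) -> float:
    """BLAST-style expect value ``E = m * n * 2**(-bits)``.

    ``db_residues`` is the total residue count of the searched database;
    E is linear in it and monotone decreasing in the bit score.
    """
    if query_len <= 0 or db_residues <= 0:
        raise AlignmentError("query_len and db_residues must be positive")
    return query_len * db_residues * math.pow(2.0, -bits)


def _wrap(result, a: str, b: str, query_id: str, subject_id: str) -> Alignment:
    qa, sa = str(result[0]), str(result[1])
    coords = result.coordinates
    return Alignment(
        query_id=query_id,
        subject_id=subject_id,
        aligned_query=qa,
        aligned_subject=sa,
        raw_score=float(result.score),
        bit_score=bit_score(float(result.score)),
        query_len=len(a),
        subject_len=len(b),
        query_start=int(coords[0][0]),
        query_end=int(coords[0][-1]),
        subject_start=int(coords[1][0]),
        subject_end=int(coords[1][-1]),
    )


def global_align(
    a: str,
    b: str,
    query_id: str = "query",
    subject_id: str = "subject",
    matrix: str = "BLOSUM62",
    gap_open: float = 11,
    gap_extend: float = 1,
) -> Alignment:
    """Optimal Needleman-Wunsch alignment with affine gaps.

    Traceback ties are resolved deterministically (first optimal path as
    enumerated by the aligner, which prefers diagonal moves).
    """
    _check_seq(a, "query")
    _check_seq(b, "subject")
    aligner = _aligner("global", matrix, gap_open, gap_extend)
    return _wrap(aligner.align(a, b)[0], a, b, query_id, subject_id)


def local_align(
    a: str,
    b: str,
    query_id: str = "query",
    subject_id: str = "subject",
    matrix: str = "BLOSUM62",
    gap_open: float = 11,
    gap_extend: float = 1,
) -> Alignment:
    """Optimal Smith-Waterman local alignment; score >= 0.

    When no residue pair scores positive the empty alignment (score 0,
    no columns) is returned.
    """
    _check_seq(a, "query")
    _check_seq(b, "subject")
    aligner = _aligner("local", matrix, gap_open, gap_extend)
    results = aligner.align(a, b)
    if len(results) == 0 or results.score <= 0:
        return Alignment(query_id, subject_id, "", "", 0.0, bit_score(0.0), len(a), len(b))
    return _wrap(results[0], a, b, query_id, subject_id)


def percent_identity(alignment: Alignment, convention: str = "alignment_columns") -> float:
    """Identity fraction under a stated denominator convention.

    ``alignment_columns``: matches / all alignment columns (gaps included).
    ``shorter_sequence``: matches / length of the shorter input sequence.
    """
    if alignment.is_empty:
        raise UndefinedIdentity("identity undefined for an empty alignment")
    if convention == "alignment_columns":
        return alignment.matches / alignment.columns
    if convention == "shorter_sequence":
        return alignment.matches / min(alignment.query_len, alignment.subject_len)
    raise ValueError(f"unknown identity convention: {convention!r}")


def percent_similarity(alignment: Alignment, matrix: str = "BLOSUM62") -> float:
    """Fraction of alignment columns with a positive substitution score.

    Offered because screening thresholds are sometimes quoted as
    "similarity" rather than identity; identical residues always count.
    """
    if alignment.is_empty:
        raise UndefinedIdentity("similarity undefined for an empty alignment")
    m = _load_matrix(matrix)
    positives = 0
    for a, b in zip(alignment.aligned_query, alignment.aligned_subject):
        if a != GAP and b != GAP and m[a, b] > 0:
            positives += 1
    return positives / alignment.columns
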