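"""Pairwise local alignment primitives.

Every sequence comparison in the toolkit — homology clustering of the
reference set, the alignment-score feature vectors fed to the SVM domain
classifiers, and homolog lookups for small subfamilies and chemotype
voting — goes through :func:`align_local`, a Smith-Waterman alignment
with affine gap penalties (biotite's C kernel).

Scores are raw substitution-matrix scores.  Where an E-value is needed
(homology calls, homolog votes) it is derived from the raw score with the
Karlin-Altschul formula ``E = K * m * n * exp(-lambda * S)`` using the
published gapped BLOSUM62/11/1 constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import biotite.sequence as bseq
import biotite.sequence.align as balign

#: Gapped Karlin-Altschul parameters for BLOSUM62, gap open 11 / extend 1.
KA_LAMBDA = 0.267
KA_K = 0.041

_AMBIGUOUS = str.maketrans({c: "X" for c in "BZJUO*"})


def _as_protein(seq: str) -> bseq.ProteinSequence:
    """Coerce to a biotite protein sequence, masking ambiguity codes to X."""
    if not seq:
        raise ValueError("cannot align an empty sequence")
    return bseq.ProteinSequence(seq.upper().translate(_AMBIGUOUS))


@lru_cache(maxsize=8)
def substitution_matrix(name: str = "BLOSUM62") -> balign.SubstitutionMatrix:
    alph = bseq.ProteinSequence.alphabet
    return balign.SubstitutionMatrix(alph, alph, name)


@dataclass(frozen=True)
class PairwiseHit:
    """Result of one local alignment.

    percent_identity is over aligned columns of the optimal local
    alignment; coverage is aligned columns / length of the shorter
    sequence, so a full-length match of the shorter sequence has
    coverage 1.0.
    """

    query_id: str
    subject_id: str
    alignment_score: int
    percent_identity: float
    coverage: float


def align_score(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> int:
    """Optimal Smith-Waterman score only (no traceback)."""
    aln = balign.align_optimal(
        _as_protein(a),
        _as_protein(b),
        substitution_matrix(matrix),
        gap_penalty=(-gap_open, -gap_extend),
        local=True,
        max_number=1,
    )[0]
    return int(aln.score)


def align_local(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
    query_id: str = "query",
    subject_id: str = "subject",
) -> PairwiseHit:
    """Optimal local alignment with identity and coverage from the traceback."""
    sa, sb = _as_protein(a), _as_protein(b)
    aln = balign.align_optimal(
        sa,
        sb,
        substitution_matrix(matrix),
        gap_penalty=(-gap_open, -gap_extend),
        local=True,
        max_number=1,
    )[0]
    n_cols = len(aln.trace)
    identity = balign.get_sequence_identity(aln, mode="all") if n_cols else 0.0
    shorter = min(len(sa), len(sb))
    return PairwiseHit(
        query_id=query_id,
        subject_id=subject_id,
        alignment_score=int(aln.score),
        percent_identity=100.0 * identity,
        coverage=n_cols / shorter,
    )


def align_span(
    query: str,
    subject: str,
    matrix: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
) -> tuple[int, int, int]:
    """(score, start, end) of the optimal local alignment on the query.

    Coordinates are 1-based inclusive residue positions of the query.
    """
    aln = balign.align_optimal(
        _as_protein(query),
        _as_protein(subject),
        substitution_matrix(matrix),
        gap_penalty=(-gap_open, -gap_extend),
        local=True,
        max_number=1,
    )[0]
    qcol = aln.trace[:, 0]
    qcol = qcol[qcol >= 0]
    if len(qcol) == 0:
        return int(aln.score), 1, 1
    return int(aln.score), int(qcol.min()) + 1, int(qcol.max()) + 1


def evalue_from_score(score: float, m: int, n: int) -> float:
    """Karlin-Altschul E-value for a raw gapped local-alignment score.

    m, n are the lengths of the two sequences.  An approximation to what
    SSEARCH/BLAST report; adequate for thresholding homolog hits.
    """
    return KA_K * m * n * math.exp(-KA_LAMBDA * score)
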