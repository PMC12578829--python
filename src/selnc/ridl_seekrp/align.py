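"""Exact Smith-Waterman local alignment with affine gaps.

The optimal local alignment is computed first; further non-overlapping
hits are found by masking the reported query interval and re-aligning
until the score drops below ``min_score``.  A gap of length L costs
``gap_open + L * gap_extend``; N (and the internal mask character) score
as a mismatch.  The dynamic programming itself is delegated to
Biopython's PairwiseAligner (exact affine-gap DP in C) configured to
this scoring model.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

_MASK_CHAR = "X"
_ALPHABET = "ACGTN" + _MASK_CHAR
_MASK_SCORE = -1e9


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment parameters; gap penalties are positive costs."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    min_score: float = 40.0
    min_length: int = 50
    min_identity: float = 0.65

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if not (self.gap_open >= self.gap_extend > 0):
            raise ValueError("need gap_open >= gap_extend > 0")


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    target_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    score: float
    identity: float

    def __post_init__(self) -> None:
        if self.q_start >= self.q_end:
            raise ValueError("q_start must be < q_end")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity must lie in [0, 1]")

    @property
    def q_length(self) -> int:
        return self.q_end - self.q_start


def _make_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            if a == _MASK_CHAR or b == _MASK_CHAR:
                matrix[a, b] = _MASK_SCORE
            elif a == "N" or b == "N":
                matrix[a, b] = scheme.mismatch
            elif a == b:
                matrix[a, b] = scheme.match
            else:
                matrix[a, b] = scheme.mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # Biopython charges open_gap_score on the first gap column and
    # extend_gap_score on each further one; our model charges open + L*ext.
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def _best_alignment(aligner: Align.PairwiseAligner, query: str, target: str):
    score = aligner.score(query, target)
    if score <= 0:
        return None, 0.0
    alignments = aligner.align(query, target)
    return alignments[0], float(score)


def local_align(
    query: str,
    target: str,
    scheme: ScoringScheme = ScoringScheme(),
    query_id: str = "query",
    target_id: str = "target",
    max_hits: int = 50,
) -> list[AlignmentHit]:
    """Iterated Smith-Waterman: optimal hit, then non-overlapping suboptimal
    hits via query masking, until the score falls below ``min_score``.

    Hits shorter than ``min_length`` (on the query) or below
    ``min_identity`` are discarded but still mask their interval so that
    weaker, longer hits elsewhere can surface.
    """
    if not query or not target:
        raise ValueError("query and target must be non-empty")
    aligner = _make_aligner(scheme)
    masked = query.upper()
    hits: list[AlignmentHit] = []
    for _ in range(max_hits):
        aln, score = _best_alignment(aligner, masked, target.upper())
        if aln is None or score < scheme.min_score:
            break
        blocks_q, blocks_t = aln.aligned
        q_start, q_end = int(blocks_q[0][0]), int(blocks_q[-1][1])
        t_start, t_end = int(blocks_t[0][0]), int(blocks_t[-1][1])
        counts = aln.counts()
        columns = counts.identities + counts.mismatches + counts.gaps
        identity = counts.identities / columns if columns else 0.0
        if q_end - q_start >= scheme.min_length and identity >= scheme.min_identity:
            hits.append(
                AlignmentHit(query_id, target_id, q_start, q_end,
                             t_start, t_end, score, identity)
            )
        masked = masked[:q_start] + _MASK_CHAR * (q_end - q_start) + masked[q_end:]
    return hits
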