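"""Pairwise protein alignment and Karlin–Altschul statistics.

Local (Smith–Waterman) and global (Needleman–Wunsch) alignment under an
affine gap model, computed by Biopython's PairwiseAligner over BLOSUM62.
A gap of length L costs ``gap_open + L * gap_extend`` (the BLAST 11/1
convention), and expectation values follow the Karlin–Altschul formula
E = K * m * n * exp(-lambda * S) with the standard gapped BLOSUM62
parameters lambda = 0.267 nats, K = 0.041.

Identity is counted over all alignment columns including gap columns
(the BLAST convention); coverage is the aligned span divided by sequence
length, reported for query and target separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

from .records import ProteinRecord


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and E-value constants."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267  # nats per raw-score unit
    K: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")

    @property
    def matrix(self):
        return _load_matrix(self.matrix_name)

    def score(self, a: str, b: str) -> float:
        return float(self.matrix[a, b])


@lru_cache(maxsize=4)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@lru_cache(maxsize=8)
def _aligner(scheme: ScoringScheme, mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = _load_matrix(scheme.matrix_name)
    # Biopython charges open_gap_score for the first gapped position and
    # extend_gap_score for each subsequent one; BLAST charges open + k*extend.
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    aligner.mode = mode
    return aligner


@dataclass(frozen=True)
class AlignmentResult:
    """One pairwise alignment with identity/coverage evidence."""

    query_id: str
    target_id: str
    raw_score: float
    identity: float
    query_coverage: float
    target_coverage: float
    aligned_pairs: tuple[tuple[int, int], ...]  # 0-based matched columns
    alignment_length: int


@dataclass(frozen=True)
class ResidueMap:
    """Reference→query position mapping induced by a global alignment.

    Positions are 1-based; the mapping is partial (gapped reference
    positions are absent) and strictly increasing where defined.
    """

    query_id: str
    reference_id: str
    mapping: dict[int, int] = field(hash=False)

    def query_position(self, reference_position: int) -> int | None:
        return self.mapping.get(reference_position)


def _require_nonempty(a: ProteinRecord, b: ProteinRecord) -> None:
    if a.length == 0 or b.length == 0:
        raise ValueError("alignment of an empty sequence is undefined")


def _summarize(query: ProteinRecord, target: ProteinRecord, alignment) -> AlignmentResult:
    blocks_q, blocks_t = alignment.aligned
    pairs: list[tuple[int, int]] = []
    n_ident = 0
    aligned_cols = 0
    for (qs, qe), (ts, te) in zip(blocks_q, blocks_t):
        for qi, ti in zip(range(qs, qe), range(ts, te)):
            pairs.append((qi, ti))
            if query.sequence[qi] == target.sequence[ti]:
                n_ident += 1
        aligned_cols += qe - qs
    if pairs:
        q_span = pairs[-1][0] - pairs[0][0] + 1
        t_span = pairs[-1][1] - pairs[0][1] + 1
        # columns = matched columns plus gap columns between blocks
        alignment_length = aligned_cols + (q_span - aligned_cols) + (t_span - aligned_cols)
    else:
        q_span = t_span = alignment_length = 0
    identity = n_ident / alignment_length if alignment_length else 0.0
    return AlignmentResult(
        query_id=query.protein_id,
        target_id=target.protein_id,
        raw_score=float(alignment.score),
        identity=identity,
        query_coverage=q_span / query.length,
        target_coverage=t_span / target.length,
        aligned_pairs=tuple(pairs),
        alignment_length=alignment_length,
    )


def local_score(a: ProteinRecord, b: ProteinRecord, scheme: ScoringScheme) -> float:
    """Optimal Smith–Waterman score only (no traceback); fast path."""
    _require_nonempty(a, b)
    return float(_aligner(scheme, "local").score(a.sequence, b.sequence))


def local_align(
    a: ProteinRecord, b: ProteinRecord, scheme: ScoringScheme
) -> AlignmentResult:
    """Optimal Smith–Waterman alignment with deterministic traceback."""
    _require_nonempty(a, b)
    alignment = _aligner(scheme, "local").align(a.sequence, b.sequence)[0]
    return _summarize(a, b, alignment)


def global_score(a: ProteinRecord, b: ProteinRecord, scheme: ScoringScheme) -> float:
    _require_nonempty(a, b)
    return float(_aligner(scheme, "global").score(a.sequence, b.sequence))


def global_align(
    a: ProteinRecord, b: ProteinRecord, scheme: ScoringScheme
) -> tuple[AlignmentResult, ResidueMap]:
    """Optimal Needleman–Wunsch alignment plus a reference-anchored map.

    The second sequence ``b`` plays the reference role in the returned
    :class:`ResidueMap` (1-based reference position -> 1-based query
    position).
    """
    _require_nonempty(a, b)
    alignment = _aligner(scheme, "global").align(a.sequence, b.sequence)[0]
    result = _summarize(a, b, alignment)
    mapping = {ti + 1: qi + 1 for qi, ti in result.aligned_pairs}
    return result, ResidueMap(a.protein_id, b.protein_id, mapping)


def evalue(score: float, m: int, n: int, scheme: ScoringScheme) -> float:
    """Karlin–Altschul expectation: E = K * m * n * exp(-lambda * score)."""
    if m < 1 or n < 1:
        raise ValueError("sequence/database lengths must be >= 1")
    return scheme.K * m * n * math.exp(-scheme.lam * score)


def score_for_evalue(target_evalue: float, m: int, n: int, scheme: ScoringScheme) -> float:
    """Smallest score whose E-value is <= target (inverse of :func:`evalue`)."""
    return math.log(scheme.K * m * n / target_evalue) / scheme.lam
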