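"""Local-alignment search harness with custom scoring matrices and e-values.

Smith-Waterman local alignment with affine gap penalties (via Biopython's
PairwiseAligner), ungapped Karlin-Altschul e-values, the minimum-alignment-
length filter (a beta-hairpin needs ~10 matched residues: two strands of at
least 5), and cumulative hit tables over a ladder of e-value thresholds —
the shape in which search specificity and sensitivity are reported.

Gap penalties are BLAST-style: a gap of length k costs open + k * extend
(defaults 11 + k). Ungapped (lambda, K) are used for gapped e-values, a
documented approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from bbtm.alphabet import AMINO_ACIDS
from bbtm.errors import ModelError
from bbtm.io_formats import SequenceRecord
from bbtm.scoring_matrices import (
    KarlinAltschulParams,
    ScoringMatrix,
    expected_score,
    karlin_altschul_params,
)

DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
DEFAULT_EVALUE = 1e-4
DEFAULT_MIN_LENGTH = 10
#: threshold ladder, most stringent first (8 rows, as in the evaluation tables)
DEFAULT_THRESHOLDS = (1e-25, 1e-20, 1e-15, 1e-10, 1e-8, 1e-6, 1e-5, 1e-4)


@dataclass(frozen=True)
class SearchHit:
    """One query-subject local alignment surviving no filters yet."""

    query_id: str
    subject_id: str
    score: float
    bit_score: float
    e_value: float
    length: int
    percent_identity: float

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("alignment length must be >= 1")
        if self.e_value <= 0:
            raise ValueError("e-value must be positive")


@dataclass
class EvaluationTable:
    """Cumulative filtered-hit counts per e-value threshold."""

    thresholds: tuple[float, ...]
    counts: list[int]

    def __post_init__(self):
        if list(self.thresholds) != sorted(self.thresholds):
            raise ValueError("thresholds must be sorted most-stringent first")
        if any(b < a for a, b in zip(self.counts, self.counts[1:])):
            raise ValueError("cumulative counts must be non-decreasing")

    def as_dict(self) -> dict[float, int]:
        return dict(zip(self.thresholds, self.counts))


def _aligner(matrix: ScoringMatrix, gap_open: float, gap_extend: float) -> PairwiseAligner:
    array = substitution_matrices.Array(alphabet=AMINO_ACIDS, dims=2)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            array[a, b] = float(matrix.scores[i, j])
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = array
    # a k-long gap scores -(open + k*extend): first residue open+extend, rest extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align(
    query: str,
    subject: str,
    matrix: ScoringMatrix,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[float, int, float]:
    """Optimal Smith-Waterman score, aligned length, and percent identity.

    Length counts all alignment columns (matches and gaps) of the optimal
    local alignment; identity is identical columns / length * 100. Returns
    ``(0.0, 0, 0.0)`` when the optimal local alignment is empty.
    """
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    aligner = _aligner(matrix, gap_open, gap_extend)
    return _align_details(aligner, query, subject)


def _align_details(aligner: PairwiseAligner, query: str, subject: str) -> tuple[float, int, float]:
    score = float(aligner.score(query, subject))
    if score <= 0:
        return 0.0, 0, 0.0
    alignment = next(iter(aligner.align(query, subject)))
    qblocks, sblocks = _aligned_blocks(alignment)
    length = identical = 0
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        for q, s in zip(query[qs:qe], subject[ss:se]):
            length += 1
            identical += q == s
    # count gap columns between aligned blocks
    for k in range(1, len(qblocks)):
        length += (qblocks[k][0] - qblocks[k - 1][1]) + (sblocks[k][0] - sblocks[k - 1][1])
    pid = 100.0 * identical / length if length else 0.0
    return score, length, pid


def _aligned_blocks(alignment):
    aligned = alignment.aligned
    return [tuple(b) for b in aligned[0]], [tuple(b) for b in aligned[1]]


def evalue(score: float, m: int, n: int, params: KarlinAltschulParams) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * score)."""
    if m < 1 or n < 1:
        raise ValueError("sequence/database lengths must be >= 1")
    return float(params.K * m * n * np.exp(-params.lam * score))


def bit_score(score: float, params: KarlinAltschulParams) -> float:
    return float((params.lam * score - np.log(params.K)) / np.log(2.0))


def filter_hits(
    hits: list[SearchHit],
    e_threshold: float = DEFAULT_EVALUE,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> list[SearchHit]:
    """Keep hits with e-value below threshold and alignment length >= min_length."""
    return [h for h in hits if h.e_value < e_threshold and h.length >= min_length]


def cumulative_hit_table(
    hits: list[SearchHit],
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> EvaluationTable:
    """Cumulative counts of length-filtered hits below each threshold."""
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted most-stringent first")
    long_enough = [h for h in hits if h.length >= min_length]
    counts = [sum(h.e_value < t for h in long_enough) for t in thresholds]
    return EvaluationTable(thresholds=tuple(thresholds), counts=counts)


@dataclass
class SearchConfig:
    gap_open: float = DEFAULT_GAP_OPEN
    gap_extend: float = DEFAULT_GAP_EXTEND
    min_length: int = DEFAULT_MIN_LENGTH
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS


def search_database(
    queries: list[SequenceRecord],
    database: list[SequenceRecord],
    matrix: ScoringMatrix,
    config: SearchConfig | None = None,
    pi: np.ndarray | None = None,
) -> list[SearchHit]:
    """Align every query against every database record and assign e-values.

    The e-value search space is query length x total database residue count.
    Refuses matrices whose expected score under the background composition is
    non-negative (local-alignment statistics undefined).
    """
    config = config or SearchConfig()
    if pi is None:
        pi = matrix.pi
    if pi is None:
        raise ValueError("background composition required for e-values")
    if expected_score(matrix, pi) >= 0:
        raise ModelError(
            "matrix has non-negative expected score; local-alignment "
            "statistics are undefined"
        )
    params = karlin_altschul_params(matrix, pi)
    n_total = sum(len(rec.residues) for rec in database)
    max_e = max(config.thresholds)
    hits: list[SearchHit] = []
    aligner = _aligner(matrix, config.gap_open, config.gap_extend)
    for q in queries:
        for s in database:
            score = float(aligner.score(q.residues, s.residues))
            if score <= 0:
                continue
            e = evalue(score, len(q.residues), n_total, params)
            if e >= max_e:
                continue
            _, length, pid = _align_details(aligner, q.residues, s.residues)
            if length == 0:
                continue
            hits.append(
                SearchHit(
                    query_id=q.id,
                    subject_id=s.id,
                    score=score,
                    bit_score=bit_score(score, params),
                    e_value=e,
                    length=length,
                    percent_identity=pid,
                )
            )
    return hits


def evaluate_matrix(
    queries: list[SequenceRecord],
    positive_db: list[SequenceRecord],
    decoy_db: list[SequenceRecord],
    matrix: ScoringMatrix,
    config: SearchConfig | None = None,
    pi: np.ndarray | None = None,
) -> tuple[EvaluationTable, EvaluationTable]:
    """Paired cumulative tables for a positive database and its decoys."""
    config = config or SearchConfig()
    pos_hits = search_database(queries, positive_db, matrix, config, pi)
    neg_hits = search_database(queries, decoy_db, matrix, config, pi)
    return (
        cumulative_hit_table(pos_hits, config.thresholds, config.min_length),
        cumulative_hit_table(neg_hits, config.thresholds, config.min_length),
    )
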