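"""Integer log-odds scoring matrices derived from a rate matrix.

A scoring matrix at evolutionary time t is the integerized log-odds table
s_ij = round( log2( P_ij(t) / pi_j ) / scale_bits ), with P(t) the transition
matrix of the estimated rate model and pi its stationary composition. Under
a reversible model P_ij(t)/pi_j is symmetric, so the matrices are symmetric
by construction. The default half-bit scale follows the BLOSUM convention.

Karlin-Altschul parameters (lambda, K) for ungapped local-alignment
statistics are computed from the integer matrix and the composition: lambda
solves sum_ij pi_i pi_j exp(lambda s_ij) = 1, and K is computed with the
standard lattice-case series over partial-sum distributions (the same
computation used for ungapped statistics in standard search tools).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from bbtm.alphabet import AMINO_ACIDS
from bbtm.ctmc_model import RateMatrix, transition_matrix
from bbtm.errors import ModelError
from bbtm.io_formats import MatrixFile

#: score assigned where P_ij(t) underflows to zero
MIN_SCORE = -16

#: published time units for the three matrix flavors: 40 for the whole-TM and
#: barrel-interior matrices, 36 for the lipid-facing matrix
DEFAULT_TIMES = {"ALL": 40.0, "IN": 40.0, "OUT": 36.0}


@dataclass
class ScoringMatrix:
    """20x20 integer log-odds matrix with its provenance."""

    scores: np.ndarray
    scale_bits: float = 0.5
    evolutionary_time: float = 0.0
    pi: np.ndarray | None = None
    comment_lines: list[str] = field(default_factory=list)

    def __post_init__(self):
        scores = np.asarray(self.scores)
        if scores.shape != (20, 20):
            raise ModelError("scoring matrix must be 20x20")
        if not np.array_equal(scores, scores.T):
            raise ModelError("scoring matrix must be symmetric")
        if not np.issubdtype(scores.dtype, np.integer):
            if not np.all(scores == np.round(scores)):
                raise ModelError("scores must be integers")
            scores = scores.astype(int)
        self.scores = scores
        if self.pi is not None:
            self.pi = np.asarray(self.pi, dtype=float)

    def to_matrix_file(self) -> MatrixFile:
        return MatrixFile(
            alphabet_order=AMINO_ACIDS,
            scores=self.scores,
            comment_lines=list(self.comment_lines),
        )

    def save(self, path) -> None:
        from bbtm.io_formats import write_matrix_file

        write_matrix_file(self.to_matrix_file(), path)

    @classmethod
    def from_matrix_file(cls, mf: MatrixFile, **kwargs) -> "ScoringMatrix":
        return cls(scores=mf.scores, comment_lines=list(mf.comment_lines), **kwargs)


@dataclass
class KarlinAltschulParams:
    """Gumbel parameters for ungapped local-alignment score statistics."""

    lam: float
    K: float
    H: float = 0.0

    def __post_init__(self):
        if self.lam <= 0 or self.K <= 0:
            raise ModelError("lambda and K must be positive")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.where(x >= 0, np.floor(x + 0.5), np.ceil(x - 0.5)).astype(int)


def derive_scoring_matrix(
    Q: RateMatrix, t: float, scale_bits: float = 0.5
) -> ScoringMatrix:
    """Integer log-odds matrix at evolutionary time t (in substitution/100-site units)."""
    if t <= 0:
        raise ValueError("evolutionary time must be positive")
    if scale_bits <= 0:
        raise ValueError("scale_bits must be positive")
    P = transition_matrix(Q, t).P
    pi = Q.pi
    with np.errstate(divide="ignore"):
        odds = np.log2(P / pi[None, :])
    raw = odds / scale_bits
    raw = 0.5 * (raw + raw.T)  # symmetric up to rounding noise by reversibility
    floored = ~np.isfinite(raw)
    if np.any(floored):
        warnings.warn(
            f"{int(np.sum(floored))} zero transition entries floored at {MIN_SCORE}",
            stacklevel=2,
        )
        raw = np.where(floored, float(MIN_SCORE), raw)
    scores = _round_half_away(raw)
    scores = np.maximum(scores, MIN_SCORE)
    return ScoringMatrix(
        scores=scores,
        scale_bits=scale_bits,
        evolutionary_time=float(t),
        pi=pi.copy(),
        comment_lines=[
            f"log-odds scoring matrix at evolutionary time t={t:g} "
            f"(expected substitutions per 100 sites)",
            f"scale: {scale_bits:g} bits per score unit; floor {MIN_SCORE}",
        ],
    )


def expected_score(matrix: ScoringMatrix | np.ndarray, pi: np.ndarray) -> float:
    """Mean per-pair score sum_ij pi_i pi_j s_ij."""
    s = matrix.scores if isinstance(matrix, ScoringMatrix) else np.asarray(matrix)
    pi = np.asarray(pi, dtype=float)
    return float(pi @ s @ pi)


def _score_distribution(s: np.ndarray, pi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Support and probabilities of the per-position score of a random pair."""
    pp = np.outer(pi, pi).ravel()
    sv = s.ravel()
    support = np.arange(sv.min(), sv.max() + 1)
    probs = np.zeros(support.shape)
    np.add.at(probs, (sv - sv.min()).astype(int), pp)
    return support, probs


def karlin_altschul_params(
    matrix: ScoringMatrix | np.ndarray,
    pi: np.ndarray | None = None,
    k_terms: int = 60,
) -> KarlinAltschulParams:
    """Solve for (lambda, K, H) of the ungapped score statistics.

    Requires a valid scoring matrix: negative expected score and at least one
    positive entry. lambda is found by root bracketing on
    f(lambda) = sum_s p(s) exp(lambda s) - 1; H = lambda E[S exp(lambda S)];
    K by the lattice-case renewal series over partial-sum distributions.
    """
    if isinstance(matrix, ScoringMatrix):
        if pi is None:
            pi = matrix.pi
        s = matrix.scores
    else:
        s = np.asarray(matrix)
    if pi is None:
        raise ValueError("composition required")
    pi = np.asarray(pi, dtype=float)
    pi = pi / pi.sum()
    mean = expected_score(s, pi)
    if mean >= 0:
        raise ModelError(
            f"invalid scoring matrix: expected score {mean:.4f} is not negative"
        )
    if s.max() <= 0:
        raise ModelError("invalid scoring matrix: no positive score entry")
    support, probs = _score_distribution(s, pi)

    def f(lam: float) -> float:
        return float(probs @ np.exp(lam * support) - 1.0)

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:  # pragma: no cover - unreachable for valid matrices
            raise ModelError("failed to bracket lambda")
    lam = float(brentq(f, 1e-12, hi, xtol=1e-12, rtol=1e-14))
    ex = np.exp(lam * support)
    H = float(lam * (probs @ (support * ex)))

    # renewal series for the lattice case: distributions of partial sums S_k
    sigma = 0.0
    lo, hi_s = int(support.min()), int(support.max())
    conv = None
    base = probs.copy()
    cur_lo = 0
    for k in range(1, k_terms + 1):
        if conv is None:
            conv, cur_lo = base.copy(), lo
        else:
            conv = np.convolve(conv, base)
            cur_lo += lo
        vals = np.arange(cur_lo, cur_lo + conv.size)
        neg = vals < 0
        term = float(conv[neg] @ np.exp(lam * vals[neg])) + float(conv[~neg].sum())
        sigma += term / k
    C = np.exp(-2.0 * sigma)
    K = C * lam / (H * (1.0 - np.exp(-lam)))
    return KarlinAltschulParams(lam=lam, K=float(K), H=H)
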