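"""Bayesian Metropolis-Hastings estimation of substitution rates.

The chain explores the 190 free off-diagonal exchangeabilities of the
reversible model (composition is fixed at the empirical alignment
composition). One randomly chosen entry is updated per step with a
multiplicative log-normal proposal (Hastings-corrected); the target is the
pruning likelihood of the alignment on its fixed tree times an independent
log-normal prior per entry.

After estimation, rates are modulated by "valid-pair" weights: the fraction
of possible unordered sequence pairs per alignment column in which the two
residue types actually co-occur, averaged over columns. Rates of residue
pairs that are rarely observed together in columns are down-weighted, which
suppresses spurious exchangeabilities for sparsely sampled pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from bbtm.ctmc_model import (
    RATE_PER_TIME_UNIT,
    PhylogeneticTree,
    RateMatrix,
    _compress_columns,
    _Propagator,
    _pruning_loglik,
    build_rate_matrix,
    check_exchangeability,
)
from bbtm.errors import EstimationError, ModelError
from bbtm.tm_dataset import LabeledAlignment, composition

_TRIU = np.triu_indices(20, k=1)


def reference_exchangeabilities() -> np.ndarray:
    """Reference exchangeabilities derived from the BLOSUM62 log-odds table.

    BLOSUM half-bit scores satisfy s_ij ~ 2 log2(q_ij / (pi_i pi_j)), so
    2**(s_ij/2) is proportional to the implied exchangeability of the pair.
    The result is normalized to mean 1 over off-diagonal entries and serves
    as the center of the default prior and as the chain initialization.
    """
    from Bio.Align import substitution_matrices

    from bbtm.alphabet import AMINO_ACIDS

    blosum = substitution_matrices.load("BLOSUM62")
    S = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            if i != j:
                S[i, j] = 2.0 ** (float(blosum[a][b]) / 2.0)
    S /= S[_TRIU].mean()
    return S


@dataclass
class PriorSpec:
    """Prior over off-diagonal exchangeabilities.

    ``reference_model``: independent log-normal on each entry, centered at
    the reference exchangeability with log-sd ``concentration``.
    ``uniform``: improper flat prior on (0, inf).
    """

    mode: str = "reference_model"
    reference: np.ndarray | None = None
    concentration: float = 1.5

    def __post_init__(self):
        if self.mode not in ("reference_model", "uniform"):
            raise ValueError(f"unknown prior mode {self.mode!r}")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.reference is None and self.mode == "reference_model":
            self.reference = reference_exchangeabilities()
        if self.reference is not None:
            self.reference = check_exchangeability(self.reference)

    def log_density(self, S: np.ndarray) -> float:
        if self.mode == "uniform":
            return 0.0
        s = S[_TRIU]
        mu = np.log(np.maximum(self.reference[_TRIU], 1e-12))
        z = (np.log(s) - mu) / self.concentration
        # log-normal logpdf up to a constant; includes the 1/s Jacobian
        return float(-0.5 * np.sum(z**2) - np.sum(np.log(s)))

    def initial_exchangeabilities(self) -> np.ndarray:
        if self.reference is not None:
            return self.reference.copy()
        S = np.ones((20, 20))
        np.fill_diagonal(S, 0.0)
        return S


@dataclass
class McmcConfig:
    """Metropolis-Hastings chain settings."""

    n_steps: int = 100_000
    burn_in_fraction: float = 0.2
    thin: int = 50
    proposal_scale: float = 1.0  # ~50% MH acceptance on simulated benchmarks
    seed: int = 0

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not 0 <= self.burn_in_fraction < 1:
            raise ValueError("burn_in_fraction must be in [0,1)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.proposal_scale < 0:
            raise ValueError("proposal_scale must be non-negative")


@dataclass
class PosteriorSample:
    """Retained draws of the exchangeability matrix plus chain diagnostics."""

    draws: list[np.ndarray]
    log_posterior: list[float]
    acceptance_rate: float
    pi: np.ndarray = field(default_factory=lambda: np.full(20, 0.05))

    def __post_init__(self):
        if len(self.draws) != len(self.log_posterior):
            raise ValueError("trace length must match number of retained draws")


def _strictly_positive_composition(pi: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    pi = np.asarray(pi, dtype=float).copy()
    pi[pi < floor] = floor
    return pi / pi.sum()


def mcmc_sample(
    aln: LabeledAlignment,
    tree: PhylogeneticTree,
    prior: PriorSpec | None = None,
    cfg: McmcConfig | None = None,
    pi: np.ndarray | None = None,
) -> PosteriorSample:
    """Run the Metropolis-Hastings chain; deterministic for a fixed seed."""
    prior = prior or PriorSpec()
    cfg = cfg or McmcConfig()
    if pi is None:
        pi = composition(aln)
    pi = _strictly_positive_composition(pi)
    indices = aln.to_indices()
    patterns, counts = _compress_columns(indices)
    rng = np.random.default_rng(cfg.seed)

    def log_target(S: np.ndarray) -> float:
        Q = build_rate_matrix(S, pi)
        prop = _Propagator(Q.matrix, Q.pi)
        ll = _pruning_loglik(patterns, counts, tree, prop, Q.pi, aln.ids)
        return ll + prior.log_density(S)

    S = prior.initial_exchangeabilities()
    if np.all(S[_TRIU] == 0):
        raise EstimationError("initial exchangeability matrix is all zero")
    current = log_target(S)
    burn_in = int(cfg.n_steps * cfg.burn_in_fraction)
    draws: list[np.ndarray] = []
    trace: list[float] = []
    accepted = accepted_post = proposed_post = 0
    n_pairs = len(_TRIU[0])
    for step in range(cfg.n_steps):
        k = rng.integers(n_pairs)
        i, j = _TRIU[0][k], _TRIU[1][k]
        old = S[i, j]
        factor = np.exp(cfg.proposal_scale * rng.standard_normal())
        new = old * factor
        S[i, j] = S[j, i] = new
        try:
            candidate = log_target(S)
        except ModelError:
            candidate = -np.inf
        # multiplicative proposal: q(old|new)/q(new|old) = new/old
        log_alpha = candidate - current + (np.log(new) - np.log(old))
        if np.log(rng.random()) < log_alpha:
            current = candidate
            accepted += 1
            if step >= burn_in:
                accepted_post += 1
        else:
            S[i, j] = S[j, i] = old
        if step >= burn_in:
            proposed_post += 1
            if (step - burn_in) % cfg.thin == 0:
                draws.append(S.copy())
                trace.append(current)
    if not draws:
        draws.append(S.copy())
        trace.append(current)
    rate = accepted / cfg.n_steps
    if cfg.proposal_scale > 0 and proposed_post > 200 and accepted_post / proposed_post < 0.005:
        raise EstimationError(
            f"chain effectively frozen: post-burn-in acceptance "
            f"{accepted_post / proposed_post:.4%}"
        )
    return PosteriorSample(
        draws=draws, log_posterior=trace, acceptance_rate=rate, pi=pi
    )


def posterior_mean_rates(sample: PosteriorSample, pi: np.ndarray | None = None) -> RateMatrix:
    """Rate matrix built from the element-wise posterior-mean exchangeabilities."""
    if not sample.draws:
        raise EstimationError("posterior sample is empty")
    if pi is None:
        pi = sample.pi
    S = np.mean(sample.draws, axis=0)
    return build_rate_matrix(S, pi)


def valid_pair_weights(aln: LabeledAlignment) -> np.ndarray:
    """Per-pair co-occurrence weights W over alignment columns.

    For column k with residue counts n_i(k) over N sequences,
    cnt_k(i,j) = n_i(k) * n_j(k) for i != j and C(n_i(k), 2) for i = j;
    w_ij = mean over columns of cnt_k(i,j) / C(N, 2), clipped to [0,1].
    Gaps and 'X' are excluded from the counts.
    """
    if aln.n_sequences < 2:
        raise ValueError("valid-pair weights need at least two sequences")
    indices = aln.to_indices()
    C = aln.width
    if C == 0:
        raise ValueError("empty alignment")
    N = aln.n_sequences
    denom = N * (N - 1) / 2.0
    W = np.zeros((20, 20))
    for k in range(C):
        col = indices[:, k]
        counts = np.bincount(col[col >= 0], minlength=20).astype(float)
        pair = np.outer(counts, counts)
        np.fill_diagonal(pair, counts * (counts - 1) / 2.0)
        W += pair / denom
    W /= C
    return np.clip(W, 0.0, 1.0)


def apply_valid_pairs(Q: RateMatrix, W: np.ndarray) -> RateMatrix:
    """Modulate off-diagonal rates by W, reset the diagonal, renormalize."""
    W = np.asarray(W, dtype=float)
    if W.shape != (20, 20):
        raise ValueError("weight matrix must be 20x20")
    if not np.allclose(W, W.T):
        raise ValueError("weight matrix must be symmetric")
    M = Q.matrix * W
    np.fill_diagonal(M, 0.0)
    if not np.any(M > 0):
        raise ValueError("all rates zero after valid-pair weighting")
    np.fill_diagonal(M, -M.sum(axis=1))
    total = float(Q.pi @ -np.diag(M))
    M *= Q.rate_unit / total
    return RateMatrix(matrix=M, pi=Q.pi, rate_unit=Q.rate_unit)


def _exchangeabilities_from_rates(Q: RateMatrix, pi: np.ndarray) -> np.ndarray:
    """Recover S from Q relative to a (possibly pooled) composition."""
    with np.errstate(divide="ignore", invalid="ignore"):
        S = Q.matrix / pi[None, :]
    np.fill_diagonal(S, 0.0)
    S = 0.5 * (S + S.T)  # exact when Q is reversible w.r.t. pi
    return S


def average_across_proteins(
    pairs: list[tuple[RateMatrix, np.ndarray]], pi: np.ndarray
) -> RateMatrix:
    """Element-wise average of per-protein rate and weight matrices.

    Per-protein rate matrices are averaged on the exchangeability scale
    relative to the supplied pooled composition (identical to element-wise
    rate averaging when all proteins share that composition), then the
    averaged valid-pair weights are applied and the result renormalized.
    """
    if not pairs:
        raise ValueError("no proteins to average")
    pi = _strictly_positive_composition(np.asarray(pi, dtype=float))
    S_mean = np.mean([_exchangeabilities_from_rates(Q, pi) for Q, _ in pairs], axis=0)
    W_mean = np.mean([np.asarray(W, dtype=float) for _, W in pairs], axis=0)
    Q_mean = build_rate_matrix(S_mean, pi)
    return apply_valid_pairs(Q_mean, W_mean)


def estimate_protein(
    aln: LabeledAlignment,
    tree: PhylogeneticTree,
    prior: PriorSpec | None = None,
    cfg: McmcConfig | None = None,
    pi: np.ndarray | None = None,
) -> tuple[RateMatrix, np.ndarray, PosteriorSample]:
    """Posterior-mean rates and valid-pair weights for one protein's columns."""
    sample = mcmc_sample(aln, tree, prior=prior, cfg=cfg, pi=pi)
    Q = posterior_mean_rates(sample)
    W = valid_pair_weights(aln)
    return Q, W, sample
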