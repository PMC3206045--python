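"""MCMC estimator behavior, valid-pair weights, and cross-protein averaging."""

import itertools

import numpy as np
import pytest
from scipy.stats import spearmanr

from bbtm.alphabet import AMINO_ACIDS
from bbtm.ctmc_model import build_rate_matrix
from bbtm.io_formats import SequenceRecord
from bbtm.rate_estimation import (
    McmcConfig,
    PosteriorSample,
    PriorSpec,
    apply_valid_pairs,
    average_across_proteins,
    mcmc_sample,
    posterior_mean_rates,
    reference_exchangeabilities,
    valid_pair_weights,
)
from bbtm.sequence_simulation import SimulationSpec, simulate_alignment
from bbtm.tm_dataset import LabeledAlignment


def _sim_alignment(tree, Q, n_columns=300, seed=9):
    return simulate_alignment(SimulationSpec(tree=tree, rates=Q, n_columns=n_columns, seed=seed))


class TestMcmc:
    def test_zero_proposal_scale_never_moves(self, quartet_tree, uniform_Q):
        aln = _sim_alignment(quartet_tree, uniform_Q, 50)
        cfg = McmcConfig(n_steps=400, proposal_scale=0.0, thin=10, seed=2)
        sample = mcmc_sample(aln, quartet_tree, cfg=cfg)
        init = PriorSpec().initial_exchangeabilities()
        for draw in sample.draws:
            assert np.array_equal(draw, init)

    def test_bitwise_reproducible(self, quartet_tree, uniform_Q):
        aln = _sim_alignment(quartet_tree, uniform_Q, 60)
        cfg = McmcConfig(n_steps=300, thin=20, seed=7)
        s1 = mcmc_sample(aln, quartet_tree, cfg=cfg)
        s2 = mcmc_sample(aln, quartet_tree, cfg=cfg)
        assert s1.log_posterior == s2.log_posterior
        assert all(np.array_equal(a, b) for a, b in zip(s1.draws, s2.draws))

    def test_recovery_beats_prior_baseline(self, quartet_tree):
        """Posterior mean ranks truth better than the prior center alone."""
        rng = np.random.default_rng(4)
        iu = np.triu_indices(20, 1)
        S0 = reference_exchangeabilities()
        S = np.zeros((20, 20))
        S[iu] = S0[iu] * np.exp(rng.normal(0, 1.0, len(iu[0])))
        S += S.T
        pi = rng.dirichlet(np.full(20, 10.0))
        truth = build_rate_matrix(S, pi)
        deep = type(quartet_tree).from_newick("((a:40,b:40):20,(c:40,d:40):20);")
        aln = _sim_alignment(deep, truth, 400, seed=3)
        sample = mcmc_sample(aln, deep, cfg=McmcConfig(n_steps=6000, seed=5))
        est = posterior_mean_rates(sample)
        prior_center = build_rate_matrix(S0, sample.pi)
        r_est = spearmanr(est.matrix[iu], truth.matrix[iu]).statistic
        r_prior = spearmanr(prior_center.matrix[iu], truth.matrix[iu]).statistic
        assert r_est > r_prior + 0.05

    def test_posterior_sample_invariant(self):
        with pytest.raises(ValueError):
            PosteriorSample(draws=[np.eye(20)], log_posterior=[], acceptance_rate=0.5)


class TestPosteriorMean:
    def test_single_draw_identity(self):
        S = reference_exchangeabilities()
        pi = np.full(20, 0.05)
        sample = PosteriorSample(draws=[S], log_posterior=[0.0], acceptance_rate=1.0, pi=pi)
        assert np.allclose(
            posterior_mean_rates(sample).matrix, build_rate_matrix(S, pi).matrix
        )

    def test_two_draws_midpoint(self):
        S1 = reference_exchangeabilities()
        S2 = 2.0 * S1
        pi = np.full(20, 0.05)
        sample = PosteriorSample(
            draws=[S1, S2], log_posterior=[0.0, 0.0], acceptance_rate=1.0, pi=pi
        )
        mid = build_rate_matrix(0.5 * (S1 + S2), pi)
        assert np.allclose(posterior_mean_rates(sample).matrix, mid.matrix)

    def test_mean_satisfies_invariants(self, quartet_tree, uniform_Q):
        aln = _sim_alignment(quartet_tree, uniform_Q, 80)
        sample = mcmc_sample(aln, quartet_tree, cfg=McmcConfig(n_steps=500, thin=10, seed=1))
        Q = posterior_mean_rates(sample)  # RateMatrix validates on construction
        assert Q.pi @ -np.diag(Q.matrix) == pytest.approx(0.01)


def _brute_force_weights(rows):
    N, C = len(rows), len(rows[0])
    W = np.zeros((20, 20))
    pairs = list(itertools.combinations(range(N), 2))
    for k in range(C):
        counts = np.zeros((20, 20))
        for a, b in pairs:
            ra, rb = rows[a][k], rows[b][k]
            if ra in AMINO_ACIDS and rb in AMINO_ACIDS:
                i, j = AMINO_ACIDS.index(ra), AMINO_ACIDS.index(rb)
                if i == j:
                    counts[i, i] += 1.0  # each identical unordered pair once
                else:
                    counts[i, j] += 1.0
                    counts[j, i] += 1.0
        W += counts / len(pairs)
    return np.clip(W / C, 0, 1)


class TestValidPairWeights:
    def test_single_mixed_column(self):
        aln = LabeledAlignment(
            [SequenceRecord(id="a", residues="A"), SequenceRecord(id="b", residues="R")]
        )
        W = valid_pair_weights(aln)
        assert W[0, 1] == W[1, 0] == 1.0

    def test_constant_column(self):
        aln = LabeledAlignment(
            [SequenceRecord(id=c, residues="A") for c in "abc"]
        )
        W = valid_pair_weights(aln)
        assert np.all(W[0, 1:] == 0) and W[0, 0] == 1.0

    def test_pair_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        rows = ["".join(rng.choice(list(AMINO_ACIDS + "-X"), 5)) for _ in range(4)]
        rows = [r if set(r) - set("-X") else "A" + r[1:] for r in rows]
        aln = LabeledAlignment(
            [SequenceRecord(id=f"s{i}", residues=r) for i, r in enumerate(rows)]
        )
        assert np.allclose(valid_pair_weights(aln), _brute_force_weights(rows))

    def test_invariant_under_reordering(self):
        rng = np.random.default_rng(3)
        rows = ["".join(rng.choice(list(AMINO_ACIDS), 8)) for _ in range(5)]
        aln1 = LabeledAlignment(
            [SequenceRecord(id=f"s{i}", residues=r) for i, r in enumerate(rows)]
        )
        perm = rng.permutation(8)
        shuffled_rows = ["".join(r[p] for p in perm) for r in rows[::-1]]
        aln2 = LabeledAlignment(
            [SequenceRecord(id=f"s{i}", residues=r) for i, r in enumerate(shuffled_rows)]
        )
        assert np.allclose(valid_pair_weights(aln1), valid_pair_weights(aln2))

    def test_single_sequence_rejected(self):
        aln = LabeledAlignment([SequenceRecord(id="a", residues="ACD")])
        with pytest.raises(ValueError):
            valid_pair_weights(aln)


class TestApplyValidPairs:
    def test_all_ones_identity(self, random_Q):
        W = np.ones((20, 20))
        assert np.allclose(apply_valid_pairs(random_Q, W).matrix, random_Q.matrix)

    def test_zero_pair_stays_zero(self, random_Q):
        W = np.ones((20, 20))
        W[2, 3] = W[3, 2] = 0.0
        Q2 = apply_valid_pairs(random_Q, W)
        assert Q2.matrix[2, 3] == 0.0 and Q2.matrix[3, 2] == 0.0

    def test_detailed_balance_preserved(self, random_Q):
        rng = np.random.default_rng(8)
        W = rng.uniform(0.1, 1.0, (20, 20))
        W = 0.5 * (W + W.T)
        Q2 = apply_valid_pairs(random_Q, W)  # validates detailed balance
        assert Q2.pi @ -np.diag(Q2.matrix) == pytest.approx(0.01)


class TestAverageAcrossProteins:
    def test_single_protein_identity(self, random_Q):
        rng = np.random.default_rng(2)
        W = rng.uniform(0.2, 1.0, (20, 20))
        W = 0.5 * (W + W.T)
        direct = apply_valid_pairs(random_Q, W)
        averaged = average_across_proteins([(random_Q, W)], random_Q.pi)
        assert np.allclose(averaged.matrix, direct.matrix, atol=1e-12)

    def test_duplicate_idempotent(self, random_Q):
        W = np.ones((20, 20))
        one = average_across_proteins([(random_Q, W)], random_Q.pi)
        two = average_across_proteins([(random_Q, W)] * 3, random_Q.pi)
        assert np.allclose(one.matrix, two.matrix)

    def test_disjoint_rates_combine(self):
        pi = np.full(20, 0.05)
        S1 = np.zeros((20, 20)); S1[0, 1] = S1[1, 0] = 1.0
        S2 = np.zeros((20, 20)); S2[2, 3] = S2[3, 2] = 1.0
        Q1, Q2 = build_rate_matrix(S1, pi), build_rate_matrix(S2, pi)
        W = np.ones((20, 20))
        avg = average_across_proteins([(Q1, W), (Q2, W)], pi)
        assert avg.matrix[0, 1] > 0 and avg.matrix[2, 3] > 0
        assert avg.matrix[0, 1] == pytest.approx(avg.matrix[2, 3])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_across_proteins([], np.full(20, 0.05))
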