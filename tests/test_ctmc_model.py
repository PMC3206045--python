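"""Rate-matrix construction, transition probabilities and pruning likelihood."""

import itertools

import numpy as np
import pytest

from bbtm.ctmc_model import (
    PhylogeneticTree,
    RateMatrix,
    build_rate_matrix,
    log_likelihood,
    stationary_distribution,
    transition_matrix,
)
from bbtm.errors import ModelError
from bbtm.io_formats import SequenceRecord
from bbtm.tm_dataset import LabeledAlignment


class TestBuildRateMatrix:
    def test_single_pair_support(self):
        S = np.zeros((20, 20))
        S[0, 1] = S[1, 0] = 1.0
        pi = np.full(20, 0.05)
        Q = build_rate_matrix(S, pi)
        nz = np.nonzero(Q.matrix - np.diag(np.diag(Q.matrix)))
        assert sorted(zip(*map(list, nz))) == [(0, 1), (1, 0)]

    def test_uniform_closed_form(self):
        S = np.ones((20, 20))
        np.fill_diagonal(S, 0.0)
        Q = build_rate_matrix(S, np.full(20, 0.05))
        off = Q.matrix[0, 1]
        assert off == pytest.approx(0.01 / 19)

    def test_detailed_balance_by_construction(self, random_Q):
        flux = random_Q.pi[:, None] * random_Q.matrix
        assert np.max(np.abs(flux - flux.T)) < 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(ModelError):
            build_rate_matrix(np.zeros((20, 20)), np.full(20, 0.05))

    def test_normalization(self, random_Q):
        assert random_Q.pi @ -np.diag(random_Q.matrix) == pytest.approx(0.01)


class TestStationary:
    def test_construction_inverse(self, random_Q):
        assert np.allclose(stationary_distribution(random_Q), random_Q.pi, atol=1e-8)

    def test_uniform(self, uniform_Q):
        assert np.allclose(stationary_distribution(uniform_Q), 0.05, atol=1e-10)

    def test_long_time_limit_oracle(self, random_Q):
        P = transition_matrix(random_Q, 1000.0).P
        limit = np.linalg.matrix_power(P, 10)  # t = 10^4
        assert np.allclose(limit, stationary_distribution(random_Q)[None, :], atol=1e-6)


class TestTransitionMatrix:
    def test_identity_at_zero(self, random_Q):
        assert np.allclose(transition_matrix(random_Q, 0.0).P, np.eye(20))

    @pytest.mark.parametrize("t", [0.1, 1.0, 40.0, 500.0])
    def test_rows_sum_to_one(self, random_Q, t):
        assert np.max(np.abs(transition_matrix(random_Q, t).P.sum(1) - 1)) < 1e-10

    def test_taylor_series_oracle(self, random_Q):
        t = 0.5
        A = random_Q.matrix * t
        series = np.zeros((20, 20))
        term = np.eye(20)
        for k in range(1, 41):
            series += term
            term = term @ A / k
        assert np.allclose(transition_matrix(random_Q, t).P, series, atol=1e-9)

    def test_negative_time_rejected(self, random_Q):
        with pytest.raises(ModelError):
            transition_matrix(random_Q, -1.0)

    def test_chapman_kolmogorov(self, random_Q):
        rng = np.random.default_rng(1)
        for s, t in rng.uniform(0, 100, size=(4, 2)):
            Ps = transition_matrix(random_Q, s).P
            Pt = transition_matrix(random_Q, t).P
            Pst = transition_matrix(random_Q, s + t).P
            assert np.allclose(Ps @ Pt, Pst, atol=1e-8)

    def test_time_reversibility(self, random_Q):
        for t in (0.5, 10.0, 200.0):
            P = transition_matrix(random_Q, t).P
            flux = random_Q.pi[:, None] * P
            assert np.allclose(flux, flux.T, atol=1e-8)


def _enumeration_loglik(aln, tree, Q):
    """Brute force: sum over all internal-node state assignments."""
    props = {i: transition_matrix(Q, tree.edge_length[i]).P for i in range(tree.n_nodes)}
    internal = [i for i in range(tree.n_nodes) if not tree.is_leaf(i)]
    leaf_state = {}
    for rec in aln.records:
        node = tree.leaf_index[rec.id]
        leaf_state[node] = rec.residues
    total = 0.0
    for col in range(aln.width):
        colsum = 0.0
        fixed = {
            node: "ARNDCQEGHILKMFPSTWYV".index(res[col])
            for node, res in leaf_state.items()
            if res[col] in "ARNDCQEGHILKMFPSTWYV"
        }
        for assign in itertools.product(range(20), repeat=len(internal)):
            states = dict(zip(internal, assign))
            states.update(fixed)
            p = Q.pi[states[tree.root]]
            for node in range(tree.n_nodes):
                if node == tree.root:
                    continue
                if node in states:
                    p *= props[node][states[tree.parent[node]], states[node]]
                else:  # missing leaf: marginalize = factor 1
                    pass
            colsum += p
        total += np.log(colsum)
    return total


class TestLogLikelihood:
    def test_single_leaf_is_log_pi(self, random_Q):
        tree = PhylogeneticTree.from_newick("(a:0.0);")
        aln = LabeledAlignment([SequenceRecord(id="a", residues="C")])
        idx = "ARNDCQEGHILKMFPSTWYV".index("C")
        assert log_likelihood(aln, tree, random_Q) == pytest.approx(
            np.log(random_Q.pi[idx])
        )

    def test_enumeration_oracle_three_leaves(self, random_Q, triplet_tree):
        rng = np.random.default_rng(5)
        rows = ["".join(rng.choice(list("ARNDC-X"), 6)) for _ in range(3)]
        rows = [r if set(r) - {"-", "X"} else "A" + r[1:] for r in rows]
        aln = LabeledAlignment(
            [SequenceRecord(id=n, residues=r) for n, r in zip("abc", rows)]
        )
        got = log_likelihood(aln, triplet_tree, random_Q)
        want = _enumeration_loglik(aln, triplet_tree, random_Q)
        assert got == pytest.approx(want, abs=1e-8)

    def test_enumeration_oracle_four_leaves(self, random_Q, quartet_tree):
        aln = LabeledAlignment(
            [SequenceRecord(id=n, residues=r) for n, r in zip("abcd", ["AC", "AD", "GC", "AW"])]
        )
        got = log_likelihood(aln, quartet_tree, random_Q)
        want = _enumeration_loglik(aln, quartet_tree, random_Q)
        assert got == pytest.approx(want, abs=1e-8)

    def test_zero_branch_degenerate_limit(self, random_Q):
        tree = PhylogeneticTree.from_newick("(a:0,b:0,c:0);")
        same = LabeledAlignment(
            [SequenceRecord(id=n, residues="W") for n in "abc"]
        )
        idx = "ARNDCQEGHILKMFPSTWYV".index("W")
        assert log_likelihood(same, tree, random_Q) == pytest.approx(
            np.log(random_Q.pi[idx]), abs=1e-6
        )
        diff = LabeledAlignment(
            [SequenceRecord(id=n, residues=r) for n, r in zip("abc", "WWY")]
        )
        assert log_likelihood(diff, tree, random_Q) <= -700

    def test_leaf_order_invariance(self, random_Q, quartet_tree):
        recs = [SequenceRecord(id=n, residues=r) for n, r in zip("abcd", ["ACD", "ABD".replace("B", "C"), "GCD", "AWD"])]
        fwd = log_likelihood(LabeledAlignment(recs), quartet_tree, random_Q)
        rev = log_likelihood(LabeledAlignment(recs[::-1]), quartet_tree, random_Q)
        assert fwd == pytest.approx(rev, abs=1e-10)

    def test_rerooting_invariance(self, random_Q):
        """Reversible model: likelihood identical for re-rootings of one unrooted tree."""
        recs = [SequenceRecord(id=n, residues=r) for n, r in zip("abcd", ["AC", "CC", "GC", "AW"])]
        aln = LabeledAlignment(recs)
        t1 = PhylogeneticTree.from_newick("((a:1,b:2):0.5,(c:3,d:4):0.5);")
        t2 = PhylogeneticTree.from_newick("(a:1,(b:2,((c:3,d:4):1):0):0);")
        t3 = PhylogeneticTree.from_newick("(c:3,(d:4,(a:1,b:2):1):0);")
        L = [log_likelihood(aln, t, random_Q) for t in (t1, t2, t3)]
        assert L[0] == pytest.approx(L[1], abs=1e-9)
        assert L[0] == pytest.approx(L[2], abs=1e-9)

    def test_unknown_leaf_rejected(self, random_Q, triplet_tree):
        aln = LabeledAlignment([SequenceRecord(id="zz", residues="A")])
        with pytest.raises(Exception, match="zz"):
            log_likelihood(aln, triplet_tree, random_Q)
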