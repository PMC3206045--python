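"""Reversible continuous-time Markov model of amino-acid substitution.

The instantaneous rate matrix is built as Q = c * S @ diag(pi), where S is a
symmetric non-negative exchangeability matrix, pi the stationary amino-acid
composition, and c a normalization constant fixing the expected number of
substitutions per site per time unit to ``RATE_PER_TIME_UNIT`` (0.01, so one
time unit corresponds to one expected residue change per 100 sites).
Transition probabilities are P(t) = expm(Q t); likelihoods over a fixed tree
use Felsenstein pruning with per-node scaling, treating gaps and 'X' as
missing data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from bbtm.alphabet import AMINO_ACIDS
from bbtm.errors import ModelError, TreeError

#: expected substitutions per site per unit of evolutionary time
RATE_PER_TIME_UNIT = 0.01
#: multiplier taking internal rates to the display scale used in rate tables
DISPLAY_SCALE = 1e4


# --- phylogenetic tree -------------------------------------------------------

class PhylogeneticTree:
    """A rooted tree with branch lengths, stored as flat arrays.

    Nodes are indexed 0..n-1 with the root last in ``postorder``. Leaves carry
    unique labels; ``edge_length[i]`` is the length of the branch above node i
    (0 for the root).
    """

    def __init__(
        self,
        parent: list[int],
        edge_length: np.ndarray,
        labels: list[str | None],
    ):
        n = len(parent)
        self.parent = list(parent)
        self.edge_length = np.asarray(edge_length, dtype=float)
        self.labels = list(labels)
        if self.edge_length.shape != (n,) or len(self.labels) != n:
            raise TreeError("inconsistent tree arrays")
        if np.any(self.edge_length < 0):
            raise TreeError("negative branch length")
        roots = [i for i, p in enumerate(parent) if p < 0]
        if len(roots) != 1:
            raise TreeError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(parent):
            if p >= 0:
                self.children[p].append(i)
        leaf_names = [lab for i, lab in enumerate(self.labels) if not self.children[i]]
        if any(name is None for name in leaf_names):
            raise TreeError("every leaf must be labeled")
        if len(set(leaf_names)) != len(leaf_names):
            dupes = sorted({n_ for n_ in leaf_names if leaf_names.count(n_) > 1})
            raise TreeError(f"duplicate leaf names: {dupes}")
        self.leaf_names: list[str] = leaf_names
        self.leaf_index = {
            lab: i for i, lab in enumerate(self.labels) if not self.children[i]
        }
        # postorder: children before parents
        order: list[int] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            order.append(node)
            stack.extend(self.children[node])
        order.reverse()
        self.postorder = order

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    @property
    def total_length(self) -> float:
        return float(self.edge_length.sum())

    @classmethod
    def from_newick(cls, text: str) -> "PhylogeneticTree":
        import dendropy

        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:
            raise TreeError(f"could not parse Newick: {exc}") from exc
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent, lengths, labels = [], [], []
        missing = 0
        for nd in nodes:
            parent.append(index[id(nd.parent_node)] if nd.parent_node else -1)
            if nd.parent_node is not None and nd.edge.length is None:
                missing += 1
                lengths.append(0.0)
            else:
                lengths.append(float(nd.edge.length or 0.0))
            if nd.is_leaf():
                labels.append(nd.taxon.label if nd.taxon else None)
            else:
                labels.append(None)
        if missing:
            warnings.warn(
                f"{missing} branch(es) without length; defaulting to 0.0", stacklevel=2
            )
        if any(L < 0 for L in lengths):
            raise TreeError("negative branch length in Newick input")
        return cls(parent, np.array(lengths), labels)

    def to_newick(self, precision: int = 6) -> str:
        def render(i: int) -> str:
            if self.is_leaf(i):
                body = self.labels[i]
            else:
                body = "(" + ",".join(render(c) for c in self.children[i]) + ")"
            if i == self.root:
                return body
            return f"{body}:{self.edge_length[i]:.{precision}f}"

        return render(self.root) + ";"

    def __repr__(self) -> str:
        return f"PhylogeneticTree({self.n_leaves} leaves, total length {self.total_length:.4g})"


# --- rate and transition matrices --------------------------------------------

def check_exchangeability(S: np.ndarray) -> np.ndarray:
    """Validate a symmetric, non-negative, zero-diagonal exchangeability matrix."""
    S = np.asarray(S, dtype=float)
    if S.shape != (20, 20):
        raise ModelError("exchangeability matrix must be 20x20")
    if not np.array_equal(S, S.T):
        raise ModelError("exchangeability matrix must be symmetric")
    if np.any(S < 0):
        raise ModelError("exchangeability entries must be non-negative")
    if np.any(np.diag(S) != 0):
        raise ModelError("exchangeability diagonal must be zero")
    return S


@dataclass
class RateMatrix:
    """Normalized instantaneous rate matrix with its stationary composition."""

    matrix: np.ndarray
    pi: np.ndarray
    rate_unit: float = RATE_PER_TIME_UNIT

    def __post_init__(self):
        Q = np.asarray(self.matrix, dtype=float)
        pi = np.asarray(self.pi, dtype=float)
        if Q.shape != (20, 20) or pi.shape != (20,):
            raise ModelError("rate matrix must be 20x20 with a 20-vector composition")
        off = Q - np.diag(np.diag(Q))
        if np.any(off < -1e-12):
            raise ModelError("off-diagonal rates must be non-negative")
        if np.max(np.abs(Q.sum(axis=1))) > 1e-10:
            raise ModelError("rate-matrix rows must sum to zero")
        flux = pi[:, None] * Q
        if np.max(np.abs(flux - flux.T)) > 1e-10:
            raise ModelError("detailed balance violated")
        total = float(pi @ -np.diag(Q))
        if abs(total - self.rate_unit) > 1e-10:
            raise ModelError(
                f"rate normalization {total:.3e} != {self.rate_unit:.3e}"
            )
        self.matrix = Q
        self.pi = pi

    def display(self) -> np.ndarray:
        """Rates on the conventional display scale (x 10^4)."""
        return self.matrix * DISPLAY_SCALE

    def to_frame(self):
        import pandas as pd

        letters = list(AMINO_ACIDS)
        return pd.DataFrame(self.display(), index=letters, columns=letters)


def build_rate_matrix(
    S: np.ndarray, pi: np.ndarray, rate_unit: float = RATE_PER_TIME_UNIT
) -> RateMatrix:
    """Build Q = c * S @ diag(pi) with rows summing to zero and fixed total rate.

    Zero composition entries are perturbed to 1e-6 and renormalized (with a
    warning) so the chain remains irreducible over the support of S.
    """
    S = check_exchangeability(S)
    pi = np.asarray(pi, dtype=float).copy()
    if pi.shape != (20,) or np.any(pi < 0):
        raise ModelError("composition must be a non-negative 20-vector")
    if np.any(pi == 0):
        warnings.warn("zero composition entries perturbed to 1e-6", stacklevel=2)
        pi[pi == 0] = 1e-6
    pi = pi / pi.sum()
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    total = float(pi @ -np.diag(Q))
    if total <= 0:
        raise ModelError("exchangeability matrix produces zero total rate")
    Q *= rate_unit / total
    return RateMatrix(matrix=Q, pi=pi, rate_unit=rate_unit)


def stationary_distribution(Q: RateMatrix | np.ndarray, atol: float = 1e-9) -> np.ndarray:
    """Left null vector of Q, normalized to sum to one.

    Raises :class:`ModelError` when the stationary distribution is not unique
    (reducible chain).
    """
    M = Q.matrix if isinstance(Q, RateMatrix) else np.asarray(Q, dtype=float)
    _, s, vh = np.linalg.svd(M.T)
    null_dim = int(np.sum(s < max(atol, s[0] * 1e-12)))
    if null_dim != 1:
        raise ModelError(f"stationary distribution not unique (null dim {null_dim})")
    v = np.abs(vh[-1])
    return v / v.sum()


@dataclass
class TransitionMatrix:
    """P(t) = expm(Q t); rows are probability distributions."""

    P: np.ndarray
    t: float

    def __post_init__(self):
        P = np.asarray(self.P, dtype=float)
        if self.t < 0:
            raise ModelError("time must be non-negative")
        if np.any(P < -1e-12) or np.any(P > 1 + 1e-12):
            raise ModelError("transition probabilities must lie in [0,1]")
        if np.max(np.abs(P.sum(axis=1) - 1)) > 1e-10:
            raise ModelError("transition-matrix rows must sum to one")
        self.P = np.clip(P, 0.0, 1.0)


class _Propagator:
    """Cached spectral decomposition of a reversible Q for fast P(t) at many t.

    A reversible Q is similar to the symmetric matrix
    B = diag(sqrt(pi)) Q diag(1/sqrt(pi)); its eigendecomposition gives
    P(t) = D^-1 V exp(w t) V^T D with D = diag(sqrt(pi)).
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        sqrt_pi = np.sqrt(pi)
        B = Q * (sqrt_pi[:, None] / sqrt_pi[None, :])
        B = 0.5 * (B + B.T)  # symmetrize away rounding noise
        self.w, self.V = np.linalg.eigh(B)
        self.left = self.V / sqrt_pi[:, None]
        self.right = (self.V * sqrt_pi[:, None]).T

    def at(self, t: float) -> np.ndarray:
        if t == 0.0:
            return np.eye(len(self.w))
        P = (self.left * np.exp(self.w * t)) @ self.right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def transition_matrix(Q: RateMatrix, t: float) -> TransitionMatrix:
    """Matrix exponential P(t) = expm(Q t) for a normalized rate matrix."""
    if t < 0:
        raise ModelError("time must be non-negative")
    P = scipy.linalg.expm(Q.matrix * t)
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return TransitionMatrix(P=P, t=float(t))


# --- pruning likelihood ------------------------------------------------------

def _compress_columns(indices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique column patterns and their multiplicities from an (N, C) index array."""
    patterns, counts = np.unique(indices.T, axis=0, return_counts=True)
    return patterns, counts


def log_likelihood(aln, tree: PhylogeneticTree, Q: RateMatrix) -> float:
    """Log-likelihood of alignment columns on a fixed tree under Q.

    Uses Felsenstein pruning over unique column patterns with per-node
    rescaling. Gaps and 'X' contribute all-ones partial vectors (missing
    data); the root prior is the stationary composition of Q.
    """
    missing = set(aln.ids) - set(tree.leaf_names)
    if missing:
        raise TreeError(f"alignment rows not on tree: {sorted(missing)}")
    indices = aln.to_indices()
    patterns, counts = _compress_columns(indices)
    prop = _Propagator(Q.matrix, Q.pi)
    return _pruning_loglik(patterns, counts, tree, prop, Q.pi, aln.ids)


def _pruning_loglik(
    patterns: np.ndarray,
    counts: np.ndarray,
    tree: PhylogeneticTree,
    prop: _Propagator,
    pi: np.ndarray,
    row_ids: list[str],
) -> float:
    npat = patterns.shape[0]
    row_of_leaf = {name: r for r, name in enumerate(row_ids)}
    partial = np.empty((tree.n_nodes, npat, 20))
    log_scale = np.zeros((tree.n_nodes, npat))
    eye = np.eye(20)
    for node in tree.postorder:
        if tree.is_leaf(node):
            name = tree.labels[node]
            if name in row_of_leaf:
                states = patterns[:, row_of_leaf[name]]
                L = np.where(states[:, None] >= 0, eye[states], 1.0)
            else:
                L = np.ones((npat, 20))  # taxon absent from alignment: missing
            partial[node] = L
        else:
            L = np.ones((npat, 20))
            scale = np.zeros(npat)
            for child in tree.children[node]:
                P = prop.at(tree.edge_length[child])
                L = L * (partial[child] @ P.T)
                scale += log_scale[child]
            mx = L.max(axis=1)
            mx = np.where(mx > 0, mx, 1.0)
            partial[node] = L / mx[:, None]
            log_scale[node] = scale + np.log(np.where(mx > 0, mx, np.finfo(float).tiny))
        if tree.is_leaf(node):
            log_scale[node] = 0.0
    root_like = partial[tree.root] @ pi
    root_like = np.maximum(root_like, np.finfo(float).tiny)
    col_loglik = np.log(root_like) + log_scale[tree.root]
    return float(np.dot(col_loglik, counts))
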