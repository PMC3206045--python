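"""Synthetic data: alignments evolved along a tree, and shuffled decoy sequences.

``simulate_alignment`` evolves i.i.d. columns down a fixed tree under a
reversible rate matrix (root states from the stationary composition, each
branch a draw from P(branch_length)); it is the ground-truth generator for
estimator parameter-recovery experiments. ``shuffle_sequence`` /
``make_decoy_database`` build composition-preserving randomized negatives,
the decoy set used to measure search specificity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from bbtm.alphabet import AMINO_ACIDS
from bbtm.ctmc_model import PhylogeneticTree, RateMatrix, _Propagator
from bbtm.io_formats import SequenceRecord
from bbtm.tm_dataset import LabeledAlignment


@dataclass
class SimulationSpec:
    """Inputs for one alignment simulation."""

    tree: PhylogeneticTree
    rates: RateMatrix
    n_columns: int
    seed: int

    def __post_init__(self):
        if self.n_columns < 1:
            raise ValueError("n_columns must be >= 1")


def simulate_alignment(spec: SimulationSpec) -> LabeledAlignment:
    """Evolve ``n_columns`` i.i.d. sites down the tree under the rate matrix.

    Deterministic for a fixed seed. Rows appear in tree-leaf order.
    """
    rng = np.random.default_rng(spec.seed)
    tree, Q = spec.tree, spec.rates
    prop = _Propagator(Q.matrix, Q.pi)
    n = spec.n_columns
    states = np.empty((tree.n_nodes, n), dtype=np.int64)
    # preorder = reversed postorder (root first, parents before children)
    for node in reversed(tree.postorder):
        if node == tree.root:
            states[node] = rng.choice(20, size=n, p=Q.pi)
        else:
            P = prop.at(tree.edge_length[node])
            parent_states = states[tree.parent[node]]
            u = rng.random(n)
            cum = np.cumsum(P, axis=1)
            states[node] = np.argmax(u[:, None] < cum[parent_states], axis=1)
    records = []
    for name in tree.leaf_names:
        node = tree.leaf_index[name]
        residues = "".join(AMINO_ACIDS[s] for s in states[node])
        records.append(SequenceRecord(id=name, residues=residues))
    return LabeledAlignment(records)


def shuffle_sequence(seq: str, seed: int) -> str:
    """Uniform random permutation of the residues (Fisher-Yates), seed-deterministic."""
    if not seq:
        raise ValueError("cannot shuffle an empty sequence")
    rng = np.random.default_rng(seed)
    chars = np.array(list(seq))
    rng.shuffle(chars)
    return "".join(chars)


def make_decoy_database(
    records: list[SequenceRecord], seed: int
) -> list[SequenceRecord]:
    """One composition-preserving shuffled copy per input record.

    Output ids carry a ``_shuffled`` suffix; each record gets its own seed
    derived from the master seed so per-record shuffles are independent yet
    reproducible.
    """
    if not records:
        raise ValueError("decoy database needs at least one input record")
    master = np.random.SeedSequence(seed)
    child_seeds = master.generate_state(len(records))
    out = []
    for rec, s in zip(records, child_seeds):
        out.append(
            SequenceRecord(
                id=f"{rec.id}_shuffled",
                residues=shuffle_sequence(rec.residues, int(s)),
                description=rec.description,
            )
        )
    return out
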