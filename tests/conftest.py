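"""Shared fixtures: small alignments, trees and rate models built in memory."""

import numpy as np
import pytest

from bbtm.ctmc_model import PhylogeneticTree, build_rate_matrix
from bbtm.io_formats import SequenceRecord
from bbtm.rate_estimation import reference_exchangeabilities
from bbtm.tm_dataset import LabeledAlignment, TMAnnotation


@pytest.fixture(scope="session")
def reference_S():
    return reference_exchangeabilities()


@pytest.fixture(scope="session")
def uniform_Q(reference_S):
    return build_rate_matrix(reference_S, np.full(20, 0.05))


@pytest.fixture(scope="session")
def random_Q():
    """A valid rate matrix with heterogeneous exchangeabilities and composition."""
    rng = np.random.default_rng(123)
    S = np.zeros((20, 20))
    iu = np.triu_indices(20, 1)
    S[iu] = rng.gamma(1.0, 1.0, size=len(iu[0]))
    S = S + S.T
    pi = rng.dirichlet(np.full(20, 5.0))
    return build_rate_matrix(S, pi)


@pytest.fixture
def quartet_tree():
    return PhylogeneticTree.from_newick("((a:10,b:10):5,(c:10,d:10):5);")


@pytest.fixture
def triplet_tree():
    return PhylogeneticTree.from_newick("((a:0.1,b:0.1):0.05,c:0.2);")


@pytest.fixture
def small_alignment():
    return LabeledAlignment(
        [
            SequenceRecord(id="a", residues="ARND-CQE"),
            SequenceRecord(id="b", residues="ARNDXCQE"),
            SequenceRecord(id="c", residues="ARKDACHE"),
        ]
    )


@pytest.fixture
def template_alignment():
    """Template with gaps plus two homologs, for TM-column extraction."""
    return LabeledAlignment(
        [
            SequenceRecord(id="tmpl", residues="AR-NDCQEGH"),
            SequenceRecord(id="h1", residues="ARWNDCQEGH"),
            SequenceRecord(id="h2", residues="AKWNECQDGH"),
        ]
    )


@pytest.fixture
def template_annotation():
    # template ungapped = ARNDCQEGH (9 residues); two strands of 3
    return TMAnnotation(
        protein_id="tmpl",
        segments=[(1, 1, 4), (2, 5, 8)],
        facing={1: "I", 2: "O", 3: "I", 5: "O", 6: "I", 7: "O"},
    )
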