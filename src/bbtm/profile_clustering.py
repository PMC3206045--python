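"""Grouping residues by similarity of their substitution profiles.

Each residue's profile is the vector of its 19 off-diagonal substitution
rates toward the other residues. Pairwise profile distances are Euclidean;
when comparing residues i and j, the coordinates for targets i and j are
excluded (the i->j rate sits at different positions in the two vectors, so a
strict 19-coordinate comparison would misalign; distances are computed over
the 18 shared target residues). Residues are then clustered by single
linkage; the dendrogram can be exported as Newick with merge heights as
node heights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from bbtm.alphabet import AMINO_ACIDS
from bbtm.ctmc_model import RateMatrix


@dataclass(frozen=True)
class SubstitutionProfile:
    """Off-diagonal substitution rates of one residue toward the other 19."""

    residue: str
    rates: np.ndarray  # length 19, display units, targets in alphabet order minus self

    def __post_init__(self):
        if self.rates.shape != (19,):
            raise ValueError("profile must have 19 entries")
        if np.any(self.rates < 0):
            raise ValueError("profile rates must be non-negative")


@dataclass
class Dendrogram:
    """Single-linkage merge history over the 20 residues.

    ``merges`` lists ``(cluster_a, cluster_b, height)`` with clusters 0..19
    the leaves (alphabet order) and cluster ``20 + k`` the result of merge k.
    """

    merges: list[tuple[int, int, float]]
    labels: str = AMINO_ACIDS

    def __post_init__(self):
        if len(self.merges) != len(self.labels) - 1:
            raise ValueError("a full dendrogram has n-1 merges")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise ValueError("single-linkage merge heights must be non-decreasing")

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for k, (a, b, h) in enumerate(self.merges):
            la = h - height[a]
            lb = h - height[b]
            node[n + k] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[n + k] = h
        return node[n + len(self.merges) - 1] + ";"

    def merge_height(self, res_a: str, res_b: str) -> float:
        """Height at which two residues first share a cluster."""
        ia, ib = self.labels.index(res_a), self.labels.index(res_b)
        members = {i: {i} for i in range(len(self.labels))}
        for k, (a, b, h) in enumerate(self.merges):
            merged = members.pop(a) | members.pop(b)
            members[len(self.labels) + k] = merged
            if ia in merged and ib in merged:
                return h
        raise RuntimeError("residues never merged")  # pragma: no cover


def substitution_profiles(Q: RateMatrix | np.ndarray) -> list[SubstitutionProfile]:
    """Row-wise off-diagonal extraction (display units) in fixed alphabet order."""
    M = Q.display() if isinstance(Q, RateMatrix) else np.asarray(Q, dtype=float)
    out = []
    for i, res in enumerate(AMINO_ACIDS):
        rates = np.delete(M[i], i)
        out.append(SubstitutionProfile(residue=res, rates=rates))
    return out


def profile_distance_matrix(profiles: list[SubstitutionProfile]) -> np.ndarray:
    """Pairwise Euclidean distances over shared target coordinates.

    For residues i and j the coordinates toward i and j themselves are
    dropped from both vectors before the Euclidean norm.
    """
    n = len(profiles)
    full = np.zeros((n, n))
    for i, p in enumerate(profiles):
        full[i] = np.insert(p.rates, i, 0.0)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            keep = [k for k in range(n) if k not in (i, j)]
            diff = full[i, keep] - full[j, keep]
            D[i, j] = D[j, i] = float(np.sqrt(np.sum(diff**2)))
    return D


def single_linkage(distances: np.ndarray) -> Dendrogram:
    """Agglomerative single-linkage clustering with deterministic tie-breaks.

    At each step the pair of clusters with the minimum inter-cluster element
    distance is merged; ties are broken by the smaller cluster index pair
    (leaves are indexed in alphabet order, merged clusters in creation order).
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or np.any(np.diag(D) != 0):
        raise ValueError("need a symmetric distance matrix with zero diagonal")
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = None
        ids = sorted(active)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                d = min(D[x, y] for x in active[a] for y in active[b])
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        merges.append((a, b, d))
        active[next_id] = active.pop(a) + active.pop(b)
        next_id += 1
    return Dendrogram(merges=merges)


def cluster_rate_matrix(Q: RateMatrix | np.ndarray) -> Dendrogram:
    """Profiles -> distances -> single-linkage, in one call."""
    return single_linkage(profile_distance_matrix(substitution_profiles(Q)))


def load_reported_tm_out_rates() -> np.ndarray:
    """Published substitution rates for the lipid-facing (TM_out) dataset.

    Symmetric 20x20 matrix in display units, assembled from the individually
    reported pair rates for lipid-facing residues. The published listing is
    partial (only the appreciable rates are reported); unreported pairs are
    zero here, so this matrix supports qualitative grouping checks, not rate
    arithmetic.
    """
    from importlib import resources

    import pandas as pd

    with resources.files("bbtm.data").joinpath("tm_out_reported_rates.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    M = np.zeros((20, 20))
    idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for _, row in df.iterrows():
        i, j = idx[row["res_a"]], idx[row["res_b"]]
        M[i, j] = M[j, i] = float(row["rate"])
    return M
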