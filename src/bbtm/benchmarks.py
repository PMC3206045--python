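"""Reproducible benchmark experiments validating the whole toolkit.

These are the package's standing validation experiments, shared by the test
suite and the acceptance script:

* ``table1_aggregates`` — aggregation of the published per-protein template
  statistics (strand counts, TM residue counts, facing-class sizes, GES
  hydrophobicity means).
* ``parameter_recovery`` — simulate alignments under a known rate matrix on
  a fixed 4-taxon tree and measure how well the Bayesian estimator recovers
  the generating rates (Spearman rank correlation, RMSE on the display
  scale).
* ``discrimination_experiment`` — derive a scoring matrix from a
  transmembrane-like rate model, then search simulated homolog families and
  their composition-preserving shuffles: positives should be recovered,
  decoys rejected.
* ``clustering_sanity`` — single-linkage clustering of the published
  lipid-facing substitution rates; the aromatic pair W and Y must group with
  each other before either joins an ionizable residue.

The experiment conditions (tree depth, truth heterogeneity, composition,
family sizes) are fixed here as the package's study conditions; see
docs/methods.md for the reasoning behind each value.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from bbtm.alphabet import AMINO_ACIDS
from bbtm.ctmc_model import PhylogeneticTree, RateMatrix, build_rate_matrix
from bbtm import rate_estimation as rates
from bbtm import sequence_simulation as sim
from bbtm import scoring_matrices as scoring
from bbtm import homology_search as search
from bbtm import profile_clustering as clustering
from bbtm import tm_dataset

_TRIU = np.triu_indices(20, k=1)

#: balanced 4-taxon recovery tree; pairwise divergences of 80-120 time units
#: sit inside the 30-90% identity band homologs are selected from
RECOVERY_TREE = "((a:40,b:40):20,(c:40,d:40):20);"
#: log-sd of the multiplicative perturbation defining the ground truth
TRUTH_LOG_SD = 1.0
#: Dirichlet concentration of the ground-truth composition
PI_CONCENTRATION = 10.0

#: beta-barrel TM-like composition: enriched G, branched aliphatics and the
#: aromatic-girdle residues Y/W; depleted ionizables and P/C
TM_LIKE_COMPOSITION = {
    "A": 0.100, "R": 0.010, "N": 0.030, "D": 0.020, "C": 0.005,
    "Q": 0.025, "E": 0.020, "G": 0.100, "H": 0.015, "I": 0.060,
    "L": 0.120, "K": 0.015, "M": 0.020, "F": 0.060, "P": 0.015,
    "S": 0.070, "T": 0.070, "W": 0.035, "Y": 0.075, "V": 0.090,
}


def tm_like_composition() -> np.ndarray:
    pi = np.array([TM_LIKE_COMPOSITION[a] for a in AMINO_ACIDS])
    return pi / pi.sum()


def make_recovery_truth(seed: int = 7) -> RateMatrix:
    """Ground-truth rate matrix: reference exchangeabilities x log-normal noise."""
    rng = np.random.default_rng(seed)
    S0 = rates.reference_exchangeabilities()
    noise = np.exp(rng.normal(0.0, TRUTH_LOG_SD, size=len(_TRIU[0])))
    S = np.zeros((20, 20))
    S[_TRIU] = S0[_TRIU] * noise
    S = S + S.T
    pi = rng.dirichlet(np.full(20, PI_CONCENTRATION))
    return build_rate_matrix(S, pi)


def parameter_recovery(
    n_columns: int,
    n_steps: int = 20_000,
    seed: int = 11,
    truth_seed: int = 7,
) -> dict:
    """Simulate under a known matrix, estimate, and compare rates to truth."""
    truth = make_recovery_truth(truth_seed)
    tree = PhylogeneticTree.from_newick(RECOVERY_TREE)
    aln = sim.simulate_alignment(
        sim.SimulationSpec(tree=tree, rates=truth, n_columns=n_columns, seed=seed)
    )
    cfg = rates.McmcConfig(n_steps=n_steps, seed=seed + 1)
    sample = rates.mcmc_sample(aln, tree, prior=rates.PriorSpec(), cfg=cfg)
    estimate = rates.posterior_mean_rates(sample)
    r = float(spearmanr(estimate.matrix[_TRIU], truth.matrix[_TRIU]).statistic)
    rmse = float(
        np.sqrt(np.mean((estimate.display()[_TRIU] - truth.display()[_TRIU]) ** 2))
    )
    return {
        "n_columns": n_columns,
        "spearman": r,
        "rmse_display": rmse,
        "acceptance": sample.acceptance_rate,
        "truth": truth,
        "estimate": estimate,
    }


def _family_tree(n_homologs: int, rng: np.random.Generator) -> PhylogeneticTree:
    """Star-like family: the query plus homologs at 20-60 time units."""
    parts = ["query:1"]
    for k in range(n_homologs):
        depth = rng.uniform(20.0, 60.0)
        parts.append(f"h{k:02d}:{depth:.2f}")
    return PhylogeneticTree.from_newick("(" + ",".join(parts) + ");")


def discrimination_experiment(
    seed: int = 5,
    n_queries: int = 3,
    n_homologs: int = 50,
    n_columns: int = 150,
    matrix_time: float = 40.0,
    e_threshold: float = 1e-4,
) -> dict:
    """Search simulated homolog families and their shuffled decoys.

    Each family is one query plus ``n_homologs`` relatives evolved from it
    along a star-like tree under a TM-like rate model; decoys are
    composition-preserving shuffles of the homologs. Returns positive
    recovery at the e-value threshold, decoy counts, the paired
    homolog-vs-decoy score comparison, and the two cumulative tables.
    """
    rng = np.random.default_rng(seed)
    Q = build_rate_matrix(rates.reference_exchangeabilities(), tm_like_composition())
    matrix = scoring.derive_scoring_matrix(Q, matrix_time)
    queries, positives = [], []
    for q in range(n_queries):
        tree = _family_tree(n_homologs, rng)
        aln = sim.simulate_alignment(
            sim.SimulationSpec(
                tree=tree, rates=Q, n_columns=n_columns, seed=int(rng.integers(2**31))
            )
        )
        by_id = {rec.id: rec for rec in aln.records}
        query = by_id["query"]
        queries.append(
            type(query)(id=f"q{q}", residues=query.residues, description="")
        )
        for rec in aln.records:
            if rec.id != "query":
                positives.append(
                    type(rec)(id=f"q{q}_{rec.id}", residues=rec.residues)
                )
    decoys = sim.make_decoy_database(positives, seed=int(rng.integers(2**31)))
    config = search.SearchConfig()
    pos_hits = search.search_database(queries, positives, matrix, config)
    neg_hits = search.search_database(queries, decoys, matrix, config)
    pos_table = search.cumulative_hit_table(pos_hits, config.thresholds, config.min_length)
    neg_table = search.cumulative_hit_table(neg_hits, config.thresholds, config.min_length)
    # recovery: fraction of family members found by their own query
    found = {
        (h.query_id, h.subject_id)
        for h in search.filter_hits(pos_hits, e_threshold, config.min_length)
    }
    n_own = sum(
        1
        for rec in positives
        for q in queries
        if rec.id.startswith(q.id + "_") and (q.id, rec.id) in found
    )
    recovery = n_own / len(positives)
    decoy_hits = len(search.filter_hits(neg_hits, e_threshold, config.min_length))
    # paired scores: each homolog vs its shuffle, same query
    pos_score = {(h.query_id, h.subject_id): h.score for h in pos_hits}
    neg_score = {(h.query_id, h.subject_id): h.score for h in neg_hits}
    wins = losses = 0
    for rec in positives:
        qid = rec.id.split("_")[0]
        p = pos_score.get((qid, rec.id), 0.0)
        d = neg_score.get((qid, rec.id + "_shuffled"), 0.0)
        if p > d:
            wins += 1
        elif d > p:
            losses += 1
    return {
        "matrix": matrix,
        "positive_recovery": recovery,
        "decoy_hits": decoy_hits,
        "n_positives": len(positives),
        "n_decoys": len(decoys),
        "positive_table": pos_table,
        "decoy_table": neg_table,
        "paired_wins": wins,
        "paired_losses": losses,
    }


def clustering_sanity() -> dict:
    """W-Y grouping check on the published lipid-facing substitution rates."""
    M = clustering.load_reported_tm_out_rates()
    dendro = clustering.cluster_rate_matrix(M)
    wy = dendro.merge_height("W", "Y")
    ionizable = {"K", "R", "D", "E", "H"}
    min_ion = min(
        min(dendro.merge_height("W", r), dendro.merge_height("Y", r))
        for r in ionizable
    )
    return {
        "wy_merge_height": wy,
        "min_aromatic_ionizable_height": min_ion,
        "wy_groups_first": wy < min_ion,
        "dendrogram": dendro,
    }


def table1_aggregates() -> dict:
    """Mean row over the published per-protein template statistics."""
    stats = tm_dataset.load_template_stats()
    mean = tm_dataset.aggregate_stats(stats)
    return {
        "n_proteins": len(stats),
        "total_strands": sum(s.n_strands for s in stats),
        "mean_tm_residues": mean.n_tm_residues,
        "mean_total_residues": mean.n_total_residues,
        "mean_in": mean.n_in,
        "mean_out": mean.n_out,
        "hydro_all": round(mean.hydro_all, 2),
        "hydro_in": round(mean.hydro_in, 2),
        "hydro_out": round(mean.hydro_out, 2),
    }
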