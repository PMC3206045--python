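# Methods

## The substitution model

Amino-acid substitution is modeled as a reversible continuous-time Markov
chain over the 20 residues. The generator is built as

    Q = c · S · Π,     q_ij = c · s_ij · π_j  (i ≠ j),   q_ii = −Σ_{j≠i} q_ij

with S a symmetric non-negative exchangeability matrix (zero diagonal), Π
the diagonal of the stationary composition π, and c a normalization constant
chosen so that the expected substitution rate Σ_i π_i(−q_ii) equals 0.01 per
site per time unit. One time unit therefore equals one expected substitution
per 100 sites, which makes the scoring-matrix times t = 40 and t = 36
directly comparable to PAM distances. Rates are displayed ×10⁴, so a
displayed value of 194 means 1.94×10⁻² substitutions per site per 100-site
time unit for that ordered pair.

Construction from (S, π) guarantees detailed balance π_i q_ij = π_j q_ji
exactly, which in turn makes the log-odds matrices below symmetric before
rounding. Transition probabilities are P(t) = exp(Qt); the hot path uses the
symmetrized eigendecomposition B = Π^{1/2} Q Π^{−1/2} (B symmetric, so
`eigh` applies) rather than a Padé `expm` per proposal, with an exact
identity shortcut at t = 0 so that impossible leaf configurations on
zero-length branches get exactly zero likelihood instead of spectral
round-off leakage.

Likelihoods on a fixed rooted tree use Felsenstein pruning over unique
column patterns, with per-node rescaling of partial likelihoods (20-state
products underflow on deep trees). Gaps and 'X' are missing data: they
contribute all-ones partial vectors and are marginalized, not treated as a
21st state. The root prior is π; by reversibility the likelihood is
invariant to root placement, which the suite checks.

## Bayesian rate estimation

The 190 free off-diagonal exchangeabilities are sampled by
Metropolis–Hastings: one uniformly chosen entry per step, multiplicative
log-normal proposal s' = s·exp(σz) with the Hastings factor s'/s, target =
pruning likelihood × prior. The composition π is fixed at the empirical
alignment composition (zeros floored at 10⁻⁶ and renormalized), following
the model's separation of composition and exchangeability.

Priors: the default (`reference_model`) is an independent log-normal on each
entry, centered on reference exchangeabilities derived from the BLOSUM62
log-odds table — half-bit scores satisfy s_ij ≈ 2·log₂(q_ij/(π_iπ_j)), so
2^(s_ij/2) is the implied exchangeability; the table is normalized to mean 1
and is also the chain initialization. This runtime-derived reference was
chosen over packaging a published general-protein rate model as constants;
any user-supplied reference matrix can be passed through `PriorSpec`. The
default log-sd (`concentration`) is 1.5: wide enough that two orders of
magnitude of deviation from the reference are reachable, narrow enough to
keep rates of never-co-observed residue pairs proper. A `uniform` mode
(improper flat prior on (0,∞)) exists for sensitivity checks; note that
under it the posterior for pairs with no data is improper and their sampled
rates drift — it is not a default for real use.

Chain defaults: 100,000 steps, 20% burn-in, thinning 50, proposal σ = 1.0.
The proposal scale was set on simulated benchmarks to give ~50–65%
acceptance; smaller scales accept ~85% of proposals and mix visibly slower.
A post-burn-in acceptance below 0.5% raises a diagnostic error. Chains are
bit-for-bit reproducible given a seed.

### Valid-pairs correction

Estimated rates are modulated by how often each residue pair is actually
co-observed in alignment columns. For column k with residue counts n_i(k)
over N sequences,

    cnt_k(i,j) = n_i(k)·n_j(k)  (i≠j),   C(n_i(k), 2)  (i=j)
    w_ij = (1/C) Σ_k cnt_k(i,j) / C(N,2),  clipped to [0,1].

Off-diagonal rates become q_ij·w_ij, the diagonal is reset and the matrix
renormalized to 0.01 so the time unit keeps its meaning. The correction
zeroes rates of pairs never seen in the same column, which is what gives the
final matrices their sparse, physico-chemically clustered look. Whether to
renormalize after correction was an open choice; renormalization was adopted
to preserve the time calibration of the derived scoring matrices.

Cross-protein averaging works on the exchangeability scale relative to a
pooled composition (identical to element-wise rate averaging when all
proteins share that composition, and well-defined when they do not), then
applies the averaged weights. The same tree per protein is reused for the
three facing-class estimations (TM_all, TM_in, TM_out).

## Scoring matrices and search statistics

Scores are half-bit integer log-odds: s_ij = round(log₂(P_ij(t)/π_j)/0.5),
ties rounded away from zero, symmetric by reversibility before rounding;
numerically zero transition entries are floored at −16 with a warning.
Defaults t = 40 (whole-TM, barrel-interior) and t = 36 (lipid-facing) follow
the published choice of the best-discriminating times; t is exposed rather
than re-derived, since the discrimination criterion behind 40/36 is not
operationalized here.

Ungapped Karlin–Altschul parameters are computed from the integer matrix and
background composition: λ is the positive root of Σ π_iπ_j e^{λ s_ij} = 1
(bracketed bisection, residual < 10⁻⁶); H = λ·E[S e^{λS}]; K uses the
lattice-case renewal series K = e^{−2σ}·λ/(H·(1−e^{−λ})) with
σ = Σ_k (1/k)(E[e^{λS_k}; S_k<0] + P(S_k ≥ 0)) over partial-sum
distributions S_k (60 convolution terms). The computation reproduces the
published ungapped (λ, K) of BLOSUM62, BLOSUM45 and PAM250 to within 0.5%,
which the suite asserts.

Search uses Smith–Waterman with affine gaps (a gap of length k costs
11 + k), e-values E = K·m·n·e^{−λS} with n the total database residue count,
a minimum alignment length of 10 (a β-hairpin: two strands of ≥5 matched
residues), and a default threshold ladder of eight e-values from 10⁻²⁵ to
10⁻⁴. Ungapped (λ, K) are applied to gapped scores — a standard, slightly
conservative approximation. Matrices with non-negative expected score are
refused (the local-alignment statistics are undefined there).

## Synthetic data and the benchmark experiments

The simulator draws root states from π and propagates each site i.i.d. down
the tree with P(branch length); there is no among-site rate variation or
indel process, matching the estimation model. Decoys are Fisher–Yates
shuffles, one per input sequence, with per-record seeds derived from a
master seed.

The standing experiments (shared by the test suite and
`scripts/acceptance.py`) fix these study conditions:

* **Parameter recovery** — balanced 4-taxon tree with 40/20 time-unit
  branches: pairwise divergences of 80–120 units sit inside the 30–90%
  identity band from which homologs are selected. Ground truth = reference
  exchangeabilities × log-normal(0, 1) perturbation; composition
  Dirichlet(10·1) (moderately non-uniform, like TM composition); estimator
  defaults at 20,000 steps. Measured behavior: Spearman r ≈ 0.66 at 500
  columns, ≈ 0.84 at 2,000, RMSE decreasing throughout. The 500-column rank
  correlation is information-limited, not estimator-limited: exact MAP
  optimization of the same posterior (L-BFGS on the 190 log rates) plateaus
  near r ≈ 0.72 at that sample size across truth heterogeneities, tree
  depths and compositions, because pairs of rare residues see essentially no
  substitution events in 500 columns of four sequences.
* **Discrimination** — three families of 50 homologs at 20–60 time units
  from their query, 150 columns, under a β-barrel-TM-like composition
  (enriched G, branched aliphatics, aromatic-girdle W/Y; depleted
  ionizables); decoys are shuffles of the homologs. The derived t = 40
  matrix recovers 100% of homologs at e < 10⁻⁴ with zero decoy hits.
* **Clustering sanity** — profiles are rows of the rate matrix without the
  diagonal; the distance between residues i and j is Euclidean over the 18
  coordinates excluding targets i and j (the i→j rate occupies different
  positions in the two 19-vectors, so a naive 19-dim comparison would
  misalign coordinates). Single linkage with deterministic tie-breaks
  (smallest cluster-index pair; leaves in alphabet order). The packaged
  lipid-facing reference rates are the pair values reported in prose —
  a partial transcription (27 pairs; values below ~3 unreported, set to 0),
  adequate for grouping checks but not for rate arithmetic.

## Numerical and edge-case choices

* Alphabet fixed to the classic PAM/NCBI order everywhere; coordinates are
  0-based half-open.
* Rounding of scores: .5 away from zero (so ±half-bit log-odds never
  collapse asymmetrically).
* `stationary_distribution` flags reducible generators (null-space dimension
  ≠ 1) instead of silently returning one of many stationary vectors.
* Annotation positions refer to the ungapped template (first) sequence;
  columns where the template is gapped are never TM columns.
* Homolog selection: half-open identity bins [30,40)…[80,90), at most two
  per bin, ties broken by higher identity then input order; any TM segment
  with more than two gaps disqualifies a hit.
* The packaged per-protein template table contains four rows whose published
  in/out counts sum to one less than the TM total (one position assigned to
  neither face); the container accepts in+out ≤ TM for loaded reference
  rows, while stats computed from alignments satisfy equality by
  construction.

## Limitations

* No among-site rate variation, no indel model, and fixed trees: rate
  estimates absorb tree-length error, and alignment uncertainty is ignored.
* Gapped e-values reuse ungapped (λ, K); absolute e-values are conservative
  rather than calibrated, though threshold *comparisons* between matrices
  are unaffected.
* The valid-pairs correction is a column co-occurrence heuristic, not a
  likelihood-based shrinkage; it can zero a genuinely nonzero rate when data
  are thin.
* Passing the synthetic benchmarks shows the estimator and search harness
  are self-consistent under the model's own assumptions; real alignments add
  misalignment, composition drift across proteins and non-i.i.d. sites that
  the generator does not emulate.
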