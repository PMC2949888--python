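# Methods

## Model

A compendium is a p×n matrix X of log-scale expression values, genes in
rows, experiments in columns. The working model is matrix normal with
Kronecker covariance,

    X ~ N_{p,n}(M, Σ ⊗ Δ),

where Σ (p×p) is gene–gene covariance, Δ (n×n) experiment–experiment
covariance, and M a mean structure removed by standardization. The
Kronecker form says gene dependence and experiment dependence act
separably: Cov(X_{ij}, X_{kl}) = Σ_{ik} Δ_{jl}. Experiment dependence
arises because projects contribute many related conditions (time
courses, dose series); it is this Δ ≠ I that inflates correlation test
statistics.

## Double standardization

`double_standardize(X, tol=0.01, max_iter=100)` iterates, in order:

1. subtract column means; 2. subtract row means;
3. divide columns by their standard deviation; 4. divide rows by theirs,

using the population (1/n) variance throughout, until the maximum
absolute entrywise change in one full sweep is below `tol`. Convergence
is typically 3–10 sweeps at the default tolerance. Constant rows or
columns are rejected up front with the offending identifier named;
non-convergence raises with the last observed delta.

Properties worth knowing:

- **Shift invariance is exact**: adding arbitrary per-row and per-column
  offsets leaves the converged matrix unchanged (the first sweep removes
  them). This is verified to ~1e-15 in the tests.
- **Rescaling invariance is false.** Multiplying rows or columns by
  positive constants changes the converged matrix (differences up to
  ~0.9 observed on random fixtures). The alternating mean/variance
  normalization has scale-dependent fixed points, unlike iterative
  proportional fitting of contingency tables. Consequence: units and
  per-array scaling conventions matter before standardization.
- **Exchangeable column dependence is annihilated.** If all experiments
  share one latent factor (every off-diagonal of Δ equal to ρ), row
  centering subtracts that factor exactly: centering k exchangeable
  variables drives every pairwise correlation to −1/(k−1) regardless of
  ρ. Double-standardized data therefore carry essentially no trace of
  compendium-wide exchangeable dependence, and n_eff computed after
  standardization cannot (and should not) correct for it. Block-wise
  (project-level) dependence, by contrast, survives standardization —
  the grand row mean removes only the average of the block factors —
  and is the structure the correction targets. Validation studies in
  this package therefore use block Δ; an exchangeable-Δ design would
  make the nominal test look well calibrated and the corrected test
  overcorrected, which is an artifact of the standardization, not a
  property of the estimator.

## Effective sample size

For a doubly standardized X, the sample correlation matrices are
Σ̂ = XXᵀ/n and Δ̂ = XᵀX/p (symmetrized). The total correlation is the
mean squared off-diagonal over unordered pairs,

    ĉ² = (2 / n(n−1)) Σ_{i<j} Δ̂_ij² / (Δ̂_ii Δ̂_jj),

with the diagonal normalization guarding against the near- (not
exactly-) unit diagonals left by a finite-tolerance standardization.
Then

    n_eff = n / (1 + (n−1) ĉ²),    p_eff = p / (1 + (p−1) α̂²),

where α̂² is the same functional of Σ̂. The variance-inflation reading:
the average of n exchangeably ĉ-correlated quantities has the variance
of n_eff independent ones.

**Efron identity.** On exactly doubly standardized data the gene-side
and experiment-side moments are tied:

    α̂² = [p(1 + ĉ²(n−1)) − n] / [n(p−1)]   ⇒   p̂_eff = n̂_eff.

`efron_identity_report` computes both sides and their discrepancy as a
standardization diagnostic. The identity holds to ~1e-12 when
standardization is run to tol 1e-10; at the default tol 0.01 the
discrepancy is of order the tolerance. Acceptance tests use tol 1e-10
fixtures for this reason.

`gene_total_correlation_sq` computes α̂² in row blocks without
materializing the p×p Σ̂ (O(block·p) memory), exact to floating point
against the dense version.

## Network inference (TRNI)

Gene-pair correlations r from Σ̂ are Fisher-transformed, z = atanh(r),
and tested two-sided against N(0, (n_used − 3)⁻¹), with
`n_mode ∈ {"neff", "nominal", <numeric>}` choosing n_used. n_used ≤ 3
is an error; |r| ≥ 1 maps to ±inf (p = 0) with a warning.

Selection is Benjamini–Hochberg step-up at level q over a declared
universe of m tests: `bh_universe="all_pairs"` (all C(p,2) pairs,
reported edges then filtered to TF-involving pairs) or `"tf_pairs"`
(only TF-involving pairs enter BH). Since n_eff < n inflates every
p-value by the same monotone map, the n_eff edge set is always a subset
of the nominal edge set at the same q.

Edge tables are deterministically ordered (p ascending, |z| descending,
then ids) with an explicit rank column; TF–TF pairs are reported once,
lexicographically oriented.

## Dependency diagnostics

- `leading_eigenvector`: eigenvector of Δ̂ for the largest eigenvalue,
  sign fixed so the largest-magnitude component is positive, ties to the
  highest index; a degenerate leading eigenvalue warns (the eigenvector
  is then an arbitrary basis choice).
- `block_permutation_test`: statistic Σ_b m_b (mean_b − grand mean)² on
  per-experiment values grouped by project, p = (1 + #{perm ≥ obs}) /
  (n_perm + 1), seed mandatory. Note the statistic is invariant to
  permutations within blocks and to block relabelings, so the attainable
  p-values are lattice-valued on small designs.
- `correlated_experiment_pairs`: Fisher test on each off-diagonal of Δ̂
  with p̂_eff (effective number of genes) as the sample size, BH over all
  C(n,2) pairs.
- `project_fcp`: fraction of significantly correlated pairs that are
  within-project, over projects of at least `min_size=4`.

## Experiment-subset search

`greedy_neff` grows a subset maximizing n_eff: the "auto" seed is the
pair with the smallest squared correlation (the 2-sample n_eff
maximizer); each step adds the candidate maximizing the enlarged
subset's n_eff, computed incrementally from the running sum of squared
pairwise correlations. Ties break to the lowest column index. A
**singleton's n_eff is defined as 1.0** (it has no pairs), so the
returned path covers every prefix of the ordering including a
single-experiment seed, and the trace length always equals the number of
experiments. `subset_neff` recomputes any subset from scratch as the
oracle. The greedy path is a heuristic: each step is exactly the
one-step argmax (verified exhaustively for n ≤ 8), but the global peak
is not guaranteed optimal.

## Synthetic generator

`matrix_normal_sample` draws X = A Z Bᵀ with A, B Cholesky factors of Σ
and Δ and Z i.i.d. N(0,1); structures are identity, exchangeable(ρ) and
blocks(sizes, ρ) with ρ ∈ [0, 1). Block Δ doubles as project structure
and emits project labels. `planted_network_sample` plants a star
topology: each target row is β·(its TF row) + σ·noise, population
TF–target correlation β/√(β²+σ²) (= 1/√2 at the β = σ = 1 default),
then mixes columns by the Cholesky factor of Δ.

What it emulates: within-project experiment correlation, a known gene
regulatory signal of tunable strength, separable gene/experiment
dependence. What it does not: non-Gaussian intensity distributions,
probe-level noise, missing values, batch mean shifts (irrelevant after
standardization), indirect regulation, feed-forward or combinatorial
motifs, autoregulation, or TF–TF coupling — every non-planted pair is an
exact null. Problem sizes used in the validation studies (p of a few
hundred to 2000, n of 30–60, 200 null replicates, 20 planted-network
seeds) are this package's own desk-scale choices; they are large enough
for the stochastic tolerances quoted in the tests.

## Evaluation

`pr_curve` scores a ranked pair list against a gold standard, matching
undirected, dropping pairs outside the gold universe (counted).
`auc10` integrates precision above a 0.10 floor over sensitivity by
trapezoid, collapsing tied sensitivities to their best precision and
anchoring at sensitivity 0.

**Evaluation universes.** A `GoldStandard` carries an optional `genes`
field: the set over which truth is complete. Curated databases leave it
unset (absence of an edge is not evidence of absence) and the universe
defaults to genes appearing in the edge list. The synthetic generator
sets it to all generated genes, so unplanted pairs count as genuine
negatives. For FDR-calibration studies (`fdr_calibration`) the BH
universe is restricted to TF-involving pairs (`bh_universe="tf_pairs"`)
so that the selection population and the evaluable population coincide;
selecting over all C(p,2) pairs but evaluating only TF-involving ones
measures the composition of the discovery list, not the realized FDR.
The discrepancy-from-ideal index (DFI) is the trapezoid integral of
|empirical FDP − nominal q| over the q-grid, skipping grid points with
no discoveries.

## Numerical conventions

float64 throughout; Gram matrices symmetrized by (M + Mᵀ)/2; population
(1/n) variances in standardization; BH implemented by sorted-threshold
scan (cross-checked against `statsmodels.stats.multitest` in the test
suite); permutation and generator randomness from
`numpy.random.default_rng` with caller-supplied seeds; all argmax/argmin
ties resolve to the lowest index; derived seeds kept below 2³¹.

## Limitations

- n_eff is a single-number summary of Δ̂; strongly non-exchangeable
  dependence within the compendium is compressed into one inflation
  factor.
- The Fisher-z null treats n_eff as if it were a real sample count;
  (n_eff − 3)⁻¹ is a plug-in variance, not an exact null.
- Standardization-sensitive preprocessing (per-array rescaling) changes
  results; see the rescaling note above.
- The greedy subset search optimizes n_eff, which is a proxy — a subset
  with higher n_eff is not guaranteed better downstream network
  recovery.
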