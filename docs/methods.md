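# Methods

This note documents the models, conventions and design choices behind
`netlayers`, in the spirit of a package reference manual. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Multilayer modularity

A cohort of L subjects over one N-parcel atlas is analysed as a multilayer
network: layer s holds subject s's weighted connectivity matrix `A_s`. A
joint partition assigns a community label `σ_is` to every node-layer pair,
scored by

    Q = (1/2μ) Σ_{ijsr} [ (A_ijs − γ V_ijs) δ_sr + ω δ_ij ] δ(σ_is, σ_jr)

with `V_ijs = k_is k_js / 2m_s` the per-layer Newman–Girvan configuration
null (`k_is` = strength of node i in layer s, `2m_s = Σ_ij A_ijs`).

**Coupling topology.** Subjects have no natural order, so the ω term is
categorical: every node is coupled to itself in *all* other layers (all
ordered layer pairs r ≠ s), not to chain-adjacent layers. An ordinal chain
would impose an arbitrary subject ordering. Consistently,
`2μ = Σ_s 2m_s + ω·N·L·(L−1)`.

**Parameters.** γ > 0 scales the null model: larger γ favors smaller,
more numerous modules per layer (dimensionless; default 1.2). ω ≥ 0 rewards
cross-layer label agreement, in the same units as the edge weights (default
0.1). The defaults are the values at which the modularity of
resting-state cohort networks of this kind peaks in a 2-D (γ, ω) search;
`grid_search` re-derives the peak for any given data over default grids
γ ∈ {0.8, 0.9, …, 1.6}, ω ∈ {0.01, 0.05, 0.1, 0.5, 1.0}, averaging achieved
Q over repeats per cell and breaking ties toward the smaller (γ, ω)
lexicographically.

**Negative weights.** Fisher-z connectivity contains negative entries, for
which the configuration null is ill-defined. By default the evaluator and
the optimizer drop negative intra-layer weights (the count is logged and
recorded in the assignment metadata) and compute `V` on the positive part —
the common convention for Fisher-z matrices. A signed variant
(`signed_null=True`) keeps the raw weights and uses signed strengths; it is
off by default and fails if a layer's total weight is non-positive. Stored
connectivity matrices always retain their negative entries; the convention
is applied only inside the community module.

## Optimizer

`louvain_optimize` is a generalized Louvain on the supra-graph (node-layer
pairs as vertices; intra-layer weights `A − γV`, inter-layer weights ω):

1. randomized single-vertex local moves until no move improves Q. Candidate
   communities are those reachable through the vertex's intra-layer edges or
   its inter-layer couplings (plus its current community) — the standard
   Louvain neighbourhood restriction, valid here because dropped-negative
   weights make non-neighbour moves non-improving;
2. aggregation to the community graph (the null and coupling terms are
   aggregated exactly) and dense-matrix Louvain on it, repeated to a fixed
   point;
3. the move/aggregate cycle restarts at vertex level until Q stops
   improving, so single node-layers can be refined after coarse merges.

Gains below 1e−10 are treated as zero; among equal gains the lowest
community label wins; vertex order is re-randomized each sweep from the
run's RNG. Achieved Q is returned with the assignment and always at least
the all-singletons Q. All randomness flows from one seed through
deterministic substreams, so every result is bit-reproducible.

## Consensus

Community labels are nominal, so "averaging assignments over runs" is
implemented as association-matrix consensus: run the optimizer `n_iter`
times (default 50), accumulate the across-run co-classification matrix over
node-layer pairs, recluster it with the same Louvain routine (γ = 1,
treating it as a single-layer graph), and repeat the recluster step on the
binary co-classification of the current partition until two successive
rounds agree (error after 100 rounds, which has not been observed; unanimity
and `n_iter = 1` reduce to the single run). The reported Q is the consensus
assignment's multilayer Q on the original network.

## Allegiance and coefficients

Each layer yields a binary co-occurrence matrix (1 where two nodes share a
label; diagonal 1). The module allegiance matrix `P` of a cohort is the
elementwise mean of its layers' co-occurrence matrices: symmetric, unit
diagonal, entries exact multiples of 1/L in [0, 1].

Against the predefined networks S (atlas labels):

    R_iS = (1/n_s)     Σ_{j∈S}  P_ij      (recruitment)
    I_iS = (1/(N−n_s)) Σ_{j∉S}  P_ij      (integration)

The recruitment sum includes j = i (`P_ii = 1`), flooring R at `1/n_s`; part
of the literature excludes the diagonal, so `include_diagonal=False`
provides that variant (divisor `n_s − 1`). With the diagonal included the
identity `n_s·R_iS + (N − n_s)·I_iS = Σ_j P_ij` holds to machine precision
and is enforced in the tests. Coefficients are computed from the consensus
assignment's per-layer labels; per-(network, hemisphere) means are exported
alongside the per-parcel values.

## Group statistics

Cohorts are compared elementwise — allegiance entries over the
`N(N−1)/2` upper triangle, and per-parcel recruitment and integration —
by shuffling cohort labels over layers while the community assignment stays
fixed. Re-detecting communities inside each shuffle would be computationally
prohibitive at usual permutation counts and is not what a label permutation
of subjects tests; the chosen reading permutes subjects after detection.

The statistic is the raw difference of group means (first-appearing group
minus the other), two-sided via absolute value by default. P-values follow
the add-one rule `p = (1 + #{|null| ≥ |obs|}) / (1 + n_perm)` and are never
zero; when the number of distinct group splits is at most the permutation
budget (default 20,000) all splits are enumerated and p is exact. BH-FDR
(step-up, q = 0.05 default) is applied per family: all upper-triangle
allegiance elements; all parcels, separately per coefficient type.

## Synthetic cohorts

The generator emulates the second-order structure the analysis consumes and
nothing more: each subject's series is T i.i.d. draws (default T = 200,
a typical resting-state run length) from a zero-mean multivariate normal
with a compound-symmetry block correlation template — `within_block_corr`
(default 0.6) inside planted communities, `between_block_corr` (default
0.15) across them. The default atlas has 200 parcels in 7 networks of sizes
(31, 35, 26, 23, 13, 30, 42) and cohorts of 32 layers.

A planted perturbation splits one network of cohort B into two subclusters
whose straddling pairs get `split_between_corr` (default 0.1). For the split
to be expressible as two communities, the straddling Fisher-z weight must
fall below the configuration-null expectation — `atanh(r_split) < γ·V̄` —
and, because sampling errors of same-block correlations are strongly
correlated, it must do so with a margin exceeding the per-layer noise of
the straddle block's mean weight (≈ 0.04 at T = 200, plus the block
jitter). Otherwise the greedy optimizer follows the layers whose noisy
margin favors merging and the split never crystallizes, even when the
layer-aggregated margin favors it. The default between-network level of
0.15 (within the typical range of empirical functional connectivity)
satisfies the margin condition at γ = 1.2; sparser backgrounds push `γ·V̄`
toward or below the straddle weight and make any within-network split
invisible to modularity — a structural property of the method worth knowing
when choosing simulation regimes.

Per-layer variability enters as one N(0, `layer_noise_sd`) offset per block
of the correlation template (default sd 0.02), emulating subject-level
differences in network coupling strength. Block-level (rather than
elementwise) jitter keeps the template comfortably positive-definite; the
smallest eigenvalue is validated before sampling and generation fails fast,
naming the parameter combination, rather than repairing the matrix. Every
layer draws from its own RNG substream keyed by (seed, group, layer), so any
layer is regenerable independently and all outputs are bit-reproducible.

What the generator does **not** model: hemodynamics, temporal
autocorrelation, motion or censoring, global signal, negative true
correlations, inter-subject topology differences beyond the planted split.
Passing tests therefore certify the analysis machinery on data with planted
second-order structure, not robustness to fMRI artifacts.

## Calibration suite

Type-I control of the permutation machinery is checked on null cohorts
(no planted difference) in a deliberately noisy regime: 20 nodes in 4
networks, 32 layers per group, within/between correlations 0.2/0.1, T = 50,
single-run detection at γ = 1.2, ω = 0, p-values at 2,000 permutations.
The regime is chosen so per-layer assignments genuinely vary (mid-range
co-classification rates): at high contrast, or after consensus averaging
(which couples a cohort's layers), elementwise co-occurrence is nearly
constant and the test degenerates to p = 1 everywhere. The pooled pre-FDR
rejection rate over six fixed seeds is compared with the 95% binomial
interval around α = 0.05 at the per-run element count; BH-FDR rejections on
null data are required to be essentially zero. Permutation p-values on such
strongly tied binary statistics remain somewhat conservative (the discrete
null piles mass on few values), which is inherent to exact permutation
tests, not an implementation artifact.

## Problem sizes

The test suite and acceptance script run the study-scale checks at 200
parcels / 7 networks / 32 layers per cohort (recovery and the planted-split
power analysis, consensus over 50 runs, 2,000 permutations) and exercise
exhaustive enumeration oracles at ≤ 6 nodes × ≤ 3 layers, where every
partition of the node-layer pairs can be scored. Enumeration-exact
permutation tests are checked at 2 + 2 layers (6 splits).

## Known limitations

- The optimizer is greedy; global optimality is verified only on enumerable
  instances (where it attains the enumerated maximum in ≥ 95% of seeded
  trials). On large networks the consensus step is the safeguard against
  run-to-run variability.
- The categorical-coupling supra-graph grows as N·L vertices and the
  consensus co-classification matrix as (N·L)²; cohorts of a few hundred
  parcels and a few dozen subjects fit comfortably in memory, but much
  larger cohorts would need a sparser consensus representation.
- Permuting subjects after a per-cohort consensus detection leaves a mild
  within-cohort dependence (all of a cohort's layers share one consensus);
  the calibration suite therefore uses single-run assignments, and the
  pipeline's per-cohort default should be read accordingly.
- Fisher-z weights are kept unthresholded except for the positive-part
  convention of the null model; results at very high γ can be sensitive to
  near-zero weights.
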