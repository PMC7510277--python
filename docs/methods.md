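# Methods

## The MCBFS objective and its updates

MCBFS is supervised attribute-weighting clustering with the clusters pinned
to the class labels. Each class center is the per-class mean (so centers are
constant across iterations), and each gene's within-class scatter is scored
through a bank of `m` bounded dissimilarities
`d_n(x, v) = 1 − exp(−γ_n (x − v)²)`. Small bandwidths `γ_n` make `d_n`
nearly proportional to the squared deviation; large ones saturate quickly and
count any appreciable deviation as ~1. Summing over samples gives the fixed
tensor `A_nk` (functions × genes), computed once per fit.

The objective

    J(W, P) = Σ_n P_n Σ_k W_k A_nk + δ Σ_k W_k² + ρ Σ_n P_n log P_n,
    W, P on their simplexes,

is minimized by alternating exact updates. Eliminating the Lagrange
multiplier of the sum-to-one constraint gives the gene update

    W_k = 1/p + (1/(2δ)) (mean_k' T_k' − T_k),   T_k = Σ_n P_n A_nk,

which enforces only the equality constraint; negative entries are clipped to
zero and the vector renormalized. Clipping-plus-renormalization is the
standard projection heuristic in attribute-weighting clustering; whether the
original method used it or another projection is not recoverable, so it is
this package's choice (logged when triggered, and the un-clipped closed form
is exposed as `raw_gene_weights` for verification). The function-weight
update is the entropy-regularized minimizer

    P_n = exp(−B_n/ρ) / Σ_n' exp(−B_n'/ρ),   B_n = Σ_k W_k A_nk,

computed with a max-shift for numerical stability (the constant −1 appearing
in the stationarity condition cancels in the normalization).

`δ` and `ρ` are re-derived at the start of each iteration from the previous
`(W, P)` so that all three objective terms share a scale:
`δ = α·(Σ_n P_n B_n)/(Σ_k W_k²)` and `ρ = β·(Σ_n P_n B_n)/|Σ_n P_n log P_n|`.
The entropy sum in the `ρ` denominator is non-positive; taking its absolute
value keeps `ρ > 0`, which is what the objective requires for the entropy
term to *discourage* collapsing onto one distance function. As printed, the
two sign conventions are contradictory; the absolute value preserves the
magnitude and the stated intent. For `m = 1` the entropy is identically zero
and a configured fallback `ρ` (default 1.0) is used with `P = (1)`.

Update order within iteration `t`: `δ, ρ` from `(W, P)^{t−1}`, then `W^t`,
then `P^t` from `W^t`. With `δ, ρ` frozen this sweep is exact block-coordinate
descent, so it never increases `J` — a property the test suite checks on 100
random instances. Across iterations `J` may move non-monotonically because
`δ, ρ` themselves change.

Initialization is uniform (`W = 1/p`, `P = 1/m`). Iteration stops when both
`max|ΔW|` and `max|ΔP|` fall below `tol` (default 1e-6) or after `max_iter`
(default 100). Ranking sorts genes by final weight, descending, with a stable
sort so ties keep input order.

## Bandwidth grid

Only the number of distance functions (`m = 50`) and the `γ_n` formula are
fixed by the method; the multipliers `σ_n` are free. The default is a
geometric grid of `m` values from 1e-2 to 1e2 (inclusive, log-spaced;
`m = 1` gives `σ = 1`), spanning sub-range to super-range length scales in
the spirit of multi-kernel learning practice. The grid is configurable
(`McbfsConfig.sigma_grid`).

## Per-gene standardization (default on)

The objective compares genes by *absolute* within-class scatter through a
single global `γ_n`, so on raw data it simply prefers genes measured on small
scales, and genes whose class means differ but whose within-class noise
matches the background are invisible to it. `fit` therefore z-scores each
gene by default (min-max scaling and raw mode are selectable): after
standardization a gene's within-class variance is `1 − (between-class
share)`, so class-informative genes are exactly the compact ones. This is
presented as the package's preprocessing choice; the upstream loading code
never transforms data. A side effect is that the ranking becomes invariant to
any global (or per-gene) affine rescaling of the input, which the suite
tests. Note the `γ_n` formula itself scales *linearly* with the data range,
so the raw (unstandardized) path is not scale-invariant — another reason the
default standardizes.

Constant (zero-range) genes would score `A_nk = 0` — spuriously optimal — and
are dropped before fitting with a warning, then appended to the ranking with
weight 0.

## Synthetic study conditions

`simulate_expression` emulates a small microarray cohort: default 60 samples,
500 genes, 20 informative, 2 balanced classes, Gaussian noise with SD 1, and
class-mean offsets `effect_size · noise_sd · (i − (c−1)/2)` so adjacent
classes differ by `effect_size` noise SDs (default 2 — a strong but realistic
differential-expression signal). Informative gene positions are drawn from
the seeded generator; sample counts are apportioned deterministically
(largest remainder). A log-normal mode provides RNA-seq-like heavy tails.
What the generator does *not* model: batch effects, gene–gene correlation,
probe saturation, dropout. Passing recovery tests on this generator shows the
algorithm finds mean-shift signal under independent Gaussian noise; it says
nothing about correlated or batch-confounded real cohorts.

`simulate_graph`'s planted-hub model overlays one node wired to `hub_degree`
random others (default 20) on an Erdős–Rényi background (default 100 nodes,
edge probability 0.02, expected background degree ≈ 2), so the hub dominates
every centrality notion with high probability.

## Centrality ensemble

The ten methods follow the conventions of the Cytoscape hub-screening
ecosystem. Conventions chosen where definitions are ambiguous:

- closeness = 1/Σdist within the node's component (unnormalized);
  eccentricity is stored as 1/ecc so every method is higher-is-central;
  radiality = Σ_w (diam + 1 − dist(v,w))/(n_comp − 1). Singleton components
  score 0 for all path-based measures.
- betweenness is unnormalized; stress counts shortest paths through the node
  (each unordered endpoint pair once).
- MCC sums (|C|−1)! over *maximal* cliques of size ≥ 2 containing the node,
  enumerated exactly; isolated nodes score 0.
- BottleNeck builds one BFS tree per root with a deterministic lowest-id
  parent rule (BFS trees are not unique); a non-root node earns a point when
  its strict descendant count exceeds a quarter of the component size. The
  strict-descendant reading is the one under which complete graphs score 0
  everywhere while long-path interior nodes collect points from every other
  root.
- EPC averages the node's component size over seeded random edge
  percolations; defaults 1000 trials at retain probability 0.5 (no published
  values exist; these are exposed as flags and the seed is mandatory for
  reproducibility).

The ensemble converts each method's scores to fractional ranks (ties get the
average rank) and averages them with configurable weights — uniform by
default, since the original weighting is not recoverable. Rank aggregation
makes the ensemble invariant to monotone rescaling of any single method.
Aggregation ties are broken by node id.

## Evaluation wrapper

kNN (default k = 5) is hand-rolled because its tie rules are pinned for
determinism: Euclidean distance, distance ties to the lower training index,
vote ties to the class of the nearest neighbor among the tied classes.
Cross-validation is stratified 10-fold repeated 10 times (fold count reduced
with a warning when the smallest class is smaller than the fold count), with
a fixed gene subset throughout — nothing is re-fit on test folds. The
positive class for Sn/Sp/F/MCC defaults to the lexicographically larger
label. Metric edge cases (zero denominators in Sn, Sp, F, MCC, kappa) return
0 with a logged warning. Exhaustive subset search evaluates all `2^g − 1`
non-empty subsets (capped at g ≤ 15), selecting by test accuracy (MCC
selectable), ties to smaller subsets then lexicographic order. The per-gene
two-sample t-test defaults to Welch's unequal-variance form (pooled
selectable) with the uncorrected p ≤ 0.05 significance rule; a
Benjamini–Hochberg flag is deliberately absent from the default path. The
key-gene filter takes externally supplied per-gene survival p-values and
keeps those with p < 0.05, ordered by p (survival analysis itself is out of
scope).

## Numerical and determinism notes

- Natural logarithm everywhere; `0·log 0 := 0`.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); the MCBFS fit itself is fully deterministic.
- CLI output headers record version, seed and parameters and contain no
  timestamps, so identical invocations are byte-identical.
- Problem sizes in tests and the acceptance script (60×500 recovery fits,
  200 seven-node oracle graphs, 10-candidate subset search) are chosen so
  the whole suite runs in seconds while the brute-force oracles stay exact.

## Known limitations

- The within-class-compactness criterion cannot see genes informative only
  through variance or higher-moment differences between classes.
- Clique enumeration and the all-pairs stress computation are exponential /
  cubic respectively; intended for post-filter networks of at most a few
  hundred nodes.
- The exact bandwidth multipliers and ensemble weights used in the original
  applications are unpublished; defaults here are principled choices, not
  reconstructions.
- Survival screening is an interface (p-value filter) only.
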