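# Methods

## Model and procedure

The package implements pathway-constrained feature selection for a two-class
expression contrast, in two stages, with an optional network-weighted
variant.

**Per-gene statistic.** For gene *i*, d_i = (x̄_d(i) − x̄_c(i)) / (s(i) + s₀)
where s(i) is the two-group pooled standard deviation

    s(i) = sqrt[ (1/n_d + 1/n_c) · (SS_d + SS_c) / (n_d + n_c − 2) ]

with SS the within-group sums of squares. The damping constant s₀ offsets
the instability of genes with very small variance: it is estimated once as
the **median of the positive pooled standard deviations** over the analyzed
gene universe, computed from the observed labeling and held fixed across
permutations so that observed and null statistics share the same damping.
(The full percentile search used by some SAM implementations, which picks
the percentile minimizing the coefficient of variation of d, is a documented
alternative; the median is the common simplification and keeps the
permutation null exactly comparable.) If every gene has zero pooled
variance, s₀ falls back to 10⁻⁶. The sign convention is case minus control;
swapping the roles negates d elementwise and changes no squared statistic.

**Set score and significance.** A gene set scores Σ d_i² over its members
(after intersection with the dataset's gene universe; sets that are empty
after intersection are retained by name but never tested). Significance is a
permutation test: sample labels are shuffled preserving class sizes, d is
recomputed (fixed s₀), and the add-one estimator
p = (1 + #{null ≥ observed}) / (B + 1) is used, so p ≥ 1/(B+1) and the test
is never anti-conservative at p = 0. Permutations are drawn uniformly with
replacement across the assignment space; an `exact=True` mode instead
enumerates all C(n, n_d) case-assignments and reports
p = #{score ≥ observed}/total (the identity assignment is part of the null).
Ties between null and observed scores count toward the numerator, with a
relative tolerance of 10⁻⁹ so that globally rescaling the statistics (e.g.
constant weights) cannot flip a tie.

**Reduction.** Within each significant set, genes are ranked by decreasing
|d| (|w·d| in the weighted variant), ties broken lexicographically by gene
ID for cross-platform determinism. For k = 1, 2, … the permutation p-value
of the residual subset (ranks k+1 … m) is computed; the loop stops at the
first k with p > c_k and the core is the first k genes. Strictly "greater
than" is used at the boundary, so c_k = 0 keeps exactly the top gene and
c_k = 1 keeps the whole set. A singleton set's core is its single gene with
no residual test. Each k draws fresh permutations from a seed derived
deterministically from (master seed, set name, k); because the sequence does
not depend on c_k, the stopping index is monotone in c_k and a tuning grid
can share one computed sequence.

**Connectivity weights.** From an undirected edge list (binary, or scored
with confidences in (0, 1]; STRING-style 0–1000 scores are divided by 1000),
w_i = 1 + Σ of incident edge scores **within the analysis universe**. Edges
touching genes outside the universe are ignored: the weight describes
connectivity among the genes actually analyzed. The unit self-loop keeps
isolated genes at w = 1, so weighting never zeroes a statistic. The weighted
statistic is w_i·d_i and the weighted set score Σ (w_i d_i)², used for both
the stage-1 screen and the reduction ranking/residual tests. With constant
weights every score scales by w² and all decisions (p-values, rankings,
stops, selections) coincide exactly with the unweighted run at the same
seed. Optional transforms log2(1+w) and rank(w) are exposed because raw hub
degrees enter the squared score as w⁴ and can dominate it; the identity
transform is the default and the literal definition.

**Tuning and classification.** c_k is chosen from a grid (default
{0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.5}) by stratified k-fold
cross-validation (default 10 folds two-class, 5 multi-class) of the
misclassification rate at the 0.5 confidence cutoff; ties go to the smaller
c_k (sparser model). A fold whose selection is empty predicts its training
majority class rather than aborting. The downstream classifier is a linear
max-margin (SVM) decision function whose margin is mapped to a case
probability by a one-dimensional logistic (Platt) calibration fitted on the
training margins — probabilities are therefore monotone in the margin and
rows sum to 1; a directly fitted regularized logistic model is available as
`kind="logistic"`. Multi-class contrasts are composed from independent
binary tasks as product probabilities (e.g. subtype × stage), which sum to
1 across the composite classes whenever each factor table does.

**Metrics.** Error rate (0.5 cutoff for two classes — a confidence of
exactly 0.5 classifies to the case class — argmax otherwise), generalized
Brier score GBS = (1/2n) ΣᵢΣₖ (Y_ik − p_ik)², belief confusion metric
BCM = (1/K) Σₖ v_k/N_k (mean confidence assigned to the true class), and
macro-averaged AUPR using step-wise average precision with confidence ties
broken by ascending sample ID. Stability is the mean pairwise Jaccard
similarity of gene (or set) lists across folds; two empty lists count as
identical, one empty against one non-empty counts 0.

## Synthetic benchmark

The generator emulates a two-class study driven by two causal genes:

* expression: iid standard normal per gene and sample (default), or rows
  resampled from a user-supplied real matrix and standardized to mean 0,
  sd 1;
* design: 1000 genes in 5 sets of 200 (disjoint by default, overlap
  configurable), 60 training and 60 test samples;
* phenotype: u = 0.37·x_weak − 0.86·x_strong, with the **threshold rule**
  (case iff u > 0) as default. A Bernoulli(sigmoid(u)) option exists, but
  with ‖β‖ ≈ 0.94 it implies ≈33% irreducible error, inconsistent with the
  low-teens test errors this design is meant to produce, so thresholding is
  the default reading;
* network: the weak-effect gene gets ~30 partners and the strong-effect
  gene ~3 (Chung–Lu expected-degree wiring); background degrees are drawn
  from a geometric distribution with mean 1.5 — a right-skewed profile
  emulating a sparse interaction network restricted to a ~1000-gene
  analysis universe, where most genes have 0–3 within-universe partners and
  a handful are moderate hubs.

Replicates derive per-replicate seeds from the master seed, so the two
method variants run on identical paired datasets. The benchmark in
`scripts/acceptance.py` uses 50 replicates per method with B = 100
permutations and 10-fold tuning — sizes chosen so a full run completes in a
few minutes on one CPU while leaving Monte-Carlo error on a 50-replicate
frequency at about ±7 points.

**What the generator does not emulate:** microarray/RNA-seq noise models,
batch effects, probe-level structure, correlated expression within pathways,
and the overlap/size heterogeneity of curated gene-set collections. Passing
the synthetic benchmark therefore demonstrates correctness and the intended
qualitative behavior of the weighting (the hub gene is rescued, the strong
gene dominates the unweighted ranking), not performance on real data.

## Numerical and design notes

* All randomness flows through derived `numpy` SeedSequence streams keyed by
  (seed, context tokens); identical inputs and seed give byte-identical
  selections, traces, and fold assignments.
* Gene-ID matching is exact, case-sensitive string equality; duplicate gene
  rows are an input error (probe collapsing is a preprocessing concern).
* Genes absent from the edge list are isolated nodes with w = 1, not errors.
* Stage-1 significance uses the raw permutation p at α = 0.05 by default; no
  multiplicity correction is applied across sets (the reduction stage, not
  the screen, controls the final sparsity).
* The dense G × G adjacency is never materialized; only row sums are
  computed.

## Known limitations

* Stage-1 power for a lone strong gene inside a large set is limited: a
  single d² ≈ 9 contribution competes with a permutation-null standard
  deviation of ≈ √(2·m·τ⁴) for an m-gene set, so with m = 200 the screen
  misses such a set in a nontrivial fraction of replicates at α = 0.05. In
  the weighted variant a high-degree gene additionally inflates the null
  variance of its own set's score through its w⁴ term, which can cost
  stage-1 power precisely when the hub carries little signal, and makes the
  residual test harder to pass after the hub is removed. Both effects are
  intrinsic to the squared-statistic construction and are visible in the
  benchmark's strong-gene selection frequencies.
* The permutation p floor 1/(B+1) interacts with small grid values: at
  B = 100 the smallest attainable p (≈0.0099) sits just below c_k = 0.01,
  so that grid point keeps more than the top gene only when the residual
  p-value is at the floor.
* The reduction is a filter-style forward procedure: strongly correlated
  neighbors of a selected gene are not discouraged from entering the core.
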