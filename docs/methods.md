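# Methods

## The problem

Biobank-scale cohorts carry hundreds of binary disease codes, most of them
extremely unbalanced: a phenotype with case–control ratio r = 0.001 in a
cohort of n = 20 000 has 20 cases.  Joint tests of K such phenotypes against
a SNP either treat the 0/1 vectors as approximately Gaussian (MANOVA and
score-based combinations, which lose power or misbehave in the extreme
tails) or fit K-dimensional regressions whose asymptotics are unreliable at
these case counts (ordinal regression of genotype on phenotypes is visibly
anti-conservative).  The approach implemented here reduces the dimension
first — grouping phenotypes by how often they co-occur as cases and merging
each group by logical OR — and only then tests, so each tested phenotype has
a workable case count and the number of tested components is small.

## Model and pipeline

**Network.** The co-occurrence network counts, for each phenotype pair
(j, k), the individuals who are cases for both: A_jk.  The diagonal A_jj is
the case count of phenotype j.  All-control individuals contribute nothing,
so A is accumulated over case-carrying rows only; this is exactly equal to
using the whole cohort (a test asserts the identity).  The similarity
W_jk = A_jk / √(A_jj A_kk) lies in [0, 1] by Cauchy–Schwarz.

**Clustering.** Complete-linkage agglomeration on the dissimilarity 1 − W
(the simplest monotone transform; linkage order depends only on the ranking
of W, and the transform is configurable in principle).  Every cut
k0 = 1..K of the dendrogram is scored by modularity

    Q(k0) = (1/2D) Σ_{j,k} (W_jk − d_j d_k / 2D) C_jk,

with d_j the degree of node j, 2D the total degree, and C_jk the
same-cluster indicator; the sum runs over all ordered pairs including
j = k, which makes Q ≡ 0 for the one-cluster partition — an identity the
tests assert on random inputs.  The partition maximizing Q is kept, ties
going to fewer clusters.  The curve is computed incrementally along the
merge sequence (each merge adds twice the inter-cluster mass of the merged
pair), which is O(K²) and agrees with re-scoring every cut from scratch
(tested).

*Self-loops.*  W has a unit diagonal (every case co-occurs with itself).
Including those self-loops in the modularity score rewards fine partitions
— each node keeps its self-loop inside its own cluster — and for extremely
sparse co-occurrence (off-diagonal W ≪ 1) the optimum degenerates toward
singletons; a network whose off-diagonal similarities are all equal would
be split into K clusters.  `select_clusters` therefore zeroes the diagonal
before scoring by default, which is the standard community-detection
convention for graphs without informative self-edges: under it, an
exchangeable similarity matrix yields one cluster and planted blocks are
recovered exactly when the co-case counts are informative (see
*Limitations*).  `include_self_loops=True` restores the literal scoring.
`modularity()` itself always evaluates the formula on exactly the matrix it
is given.

**Merging and testing.** Cluster l's merged phenotype is the element-wise
maximum of its members' case indicators, so its case count is at least any
member's.  The score statistic per cluster is

    T_l = √n · corr(x, Y_l),

i.e. the locally most powerful score test of the genotype coefficient in
the identity-link model, normalized so Var(T_l) → 1 under the null.  (The
normalization is the one interpretive choice in the test statistic; it is
forced by the requirement that the omnibus form below be χ²_L-calibrated,
and the null Kolmogorov–Smirnov checks confirm it.)  The omnibus statistic
T Σ̂⁻¹ Tᵀ uses the Pearson correlation matrix Σ̂ of the merged phenotypes as
the estimate of cor(T); since each T_l is linear in Y_l given x, this is
consistent under the null.  p-values come from the χ²_L upper tail.

**Covariates.** Genotype and merged phenotypes are replaced by their
least-squares residuals against (intercept, covariates) before testing;
merged phenotypes then enter the correlation-form score test as continuous
variables.  Σ̂ is computed on the same residualized vectors that enter the
score tests, for internal consistency.  There is no logistic-link covariate
path and no mixed model.

**Degenerate inputs.** Phenotypes with zero cases are dropped with a
warning before network construction.  A merged phenotype that is constant
(possible after subsetting) is dropped with a warning and the degrees of
freedom reduced.  If Σ̂'s condition number exceeds 10⁸ a ridge of 10⁻⁸ is
added to its diagonal with a warning — duplicate merged phenotypes should
not survive community detection, but a genome-wide scan must not crash.
Liability ties at the dichotomization threshold (probability zero under the
continuous model) are broken toward smaller row indices, deterministically.

## Comparators

* **MANOVA** — one-predictor Wilks' Λ = 1 − R²(x on the phenotype span),
  computed from centered cross-products (accumulated over case-carrying
  rows when the phenotypes are rare, which keeps scans cheap), referred to
  χ²_K via Bartlett's −(n − 1 − (K+2)/2)·log Λ.  Cross-checked against
  statsmodels' MANOVA to machine precision in the tests.
* **USAT** — min-p combination of the score-form MANOVA statistic
  U V⁻¹ Uᵀ and the sum of squared per-phenotype scores (SSU) over the
  weight grid w ∈ {0, 0.1, …, 1}.  Under the null every T_w is a weighted
  quadratic form with weights w + (1 − w)λ_i (λ = eigenvalues of the
  phenotype correlation matrix); per-w p-values use the three-moment
  shifted-scaled chi-square match (a χ²_d with matched scale, shift, and
  df — the standard refinement of the "shifted scaled χ²₁" description).
  The min-p statistic is calibrated by one-dimensional integration over
  the χ²_K MANOVA component treating the SSU component as independent;
  ignoring their positive dependence underestimates the joint survival
  and therefore errs conservative, which matches the known conservatism
  of USAT with extremely unbalanced phenotypes.
* **TATES** — per-phenotype two-sided score-test p-values combined by the
  extended Simes rule min_i (K_e p_(i) / K_e,i).  The p-value correlation
  matrix is approximated from the phenotype correlation r by the published
  sixth-order polynomial (−0.0009 r + 0.6281 r² + 0.0099 r³ + 0.0588 r⁴
  − 0.0127 r⁵ + 0.2982 r⁶), with |r| = 1 pinned to exactly 1; effective
  numbers are K minus the excess over 1 of the large eigenvalues.  Both
  ingredients follow the original TATES construction.
* **MultiPhen** — proportional-odds (cumulative logit) regression of the
  genotype categories on all K phenotypes, likelihood-ratio χ²_K against
  the intercepts-only model (whose MLE is the empirical category
  distribution).  The fit is Fisher scoring with step-halving, iteration
  cap 100, gradient tolerance 10⁻⁸; identical phenotype rows are collapsed
  into weighted pseudo-observations first — with rare phenotypes the
  all-zero row covers ~98% of the cohort, which is what makes ordinal fits
  at n = 20 000, K = 100 feasible (~20 ms instead of seconds).  Genotypes
  with two observed categories degrade to binary logistic regression.
  Non-convergence is flagged on the result, never raised.  The
  log-likelihood agrees with statsmodels' OrderedModel in the tests.

These are implementations from the published descriptions for simulation
comparison; they are not ports of the original authors' code.

## Synthetic data

The generator emulates the standard simulation design for correlated
unbalanced phenotypes:

* Genotypes: minor-allele counts Binomial(2, MAF) — Hardy–Weinberg
  equilibrium; default MAF 0.3.
* Liabilities: y = λx + c·γf + √(1 − c²)·ε with R exchangeable factors
  (cov (1 − ρ)I + ρJ, realised as a shared-component construction for
  ρ ≥ 0), 0/1 block loadings γ, iid N(0,1) residuals.  Defaults c² = 0.4
  (within-factor phenotype correlation) and ρc² = 0.24 (between-factor).
* Effect configurations (model_id 1–5): five factors with effects on the
  last two (equal; opposite; opposite with a linear taper), ten factors
  with four affected (two with triangular tapers ±β/(k/2+1)·(1..k/2,k/2..1),
  two constant ±β), and fifty two-phenotype factors with ±β on the last
  ten.  β = 0 is the global null.
* Case status: per phenotype, the top round(n·r) liabilities are cases —
  a liability threshold giving exactly the target case count (all standard
  settings make n·r integral; rounding is round-half-to-even).

What it does **not** emulate: linkage disequilibrium or multiple causal
SNPs, population structure or relatedness, missing phenotypes, informative
covariates, or diagnostic-code noise.  Passing calibration tests on these
data therefore show correctness of the statistical machinery under the
stated factor model, not robustness to real-biobank artifacts.

Randomness: every study derives the replicate-i stream from
`SeedSequence([master_seed, i])`; genotypes then liabilities consume one
stream in fixed order, so results are independent of execution order and
chunking, and bit-identical across reruns.  The harness draws liabilities
in float32 (the threshold step uses only ranks; the public generator
defaults to float64), and co-occurrence counts accumulate via float32 BLAS
products, exact below 2²⁴.

## Study sizes and tolerances

The packaged calibration runs use Monte-Carlo sizes chosen to give
3-standard-error bands a few times tighter than the effects being checked:
5 000 null replicates for the n = 20 000, r = 0.001 design (α = 0.05 and
0.01 rates), 2 000 replicates for the r = 0.002 and n = 30 000 designs and
for the comparator calibration pattern, 500 replicates per point for power
ordering, and 1 000 replicates for the uniformity (KS) check at a reduced
design (n = 5 000, K = 20, r = 0.01).  Each estimate is reported with its
binomial standard error; the display convention for bands follows
α ± 1.96·√(α(1−α)/reps).

The power-curve effect grid defaults to β ∈ {0.05, 0.075, 0.1, 0.125,
0.15} at n = 20 000, r = 0.002, where MLN-O's power spans roughly 0.3 to 1;
the grid is a parameter, not a constant of the method.

## Limitations

* At r = 0.002 and n = 20 000 a phenotype has 40 cases and within-factor
  co-case counts are ~3; the co-occurrence network is then too noisy for
  the modularity optimum to recover the planted five-block structure — it
  fragments blocks into sub-clusters (L ≈ 10–20).  This does not affect
  test calibration (the omnibus is χ²_L for whatever L is chosen) and the
  power advantage persists, but exact block recovery needs denser cases
  (recovery is exact at r = 0.01 in the tests).  Merging sub-clusters of a
  true block simply splits its signal across a few well-calibrated tests.
* The modularity score cannot split a two-phenotype network under the
  default (no-self-loop) convention — a known degeneracy of modularity;
  with two phenotypes use `include_self_loops=True` or supply a partition.
* The method is designed for *unbalanced* phenotypes; with common
  phenotypes the merged indicators saturate at 1 and the approach is not
  appropriate.
* USAT's min-p calibration is an approximation (see above); it is
  deliberately conservative rather than exact.
* Score tests rely on large-sample normality of case-count sums; at case
  counts below ~10 per *merged* phenotype the χ² calibration degrades.
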