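# Methods

## The association model

`wchc` tests whether a single biallelic variant is associated with a set of M
correlated quantitative phenotypes measured on N unrelated individuals. The
test is built from three pieces: a hierarchical clustering of the phenotypes,
an optimally weighted phenotype combination within each cluster scored
against an allele-level genotype coding, and a min-p combination of the
per-cluster permutation p-values.

### Allele expansion and the cluster statistic

Each genotype g_i ∈ {0, 1, 2} (minor-allele count) is expanded into two
binary allele indicators: AA → (1, 1), Aa → (1, 0), aa → (0, 0), and the
individual's phenotype row is duplicated, giving 2N allele records
(x_l, y_l1, …, y_lM). The motivating model is the allele-based logistic
regression

    logit P(x_l = 1 | y_l) = β0 + β1 y_l1 + … + βM y_lM ,

but the logistic model is never fitted. Instead, within a phenotype cluster
C_k the statistic is the score of the weighted combination
y_l = Σ_{j∈C_k} w_j y_lj,

    T_k = Σ_l (x_l − x̄)(y_l − ȳ),
    w_j = Σ_l (x_l − x̄)(y_lj − ȳ_j) / Σ_l (y_lj − ȳ_j)² ,

which collapses algebraically to T_k = Σ_{j∈C_k} c_j²/v_j, with c_j the
centred x–y_j cross sum and v_j the centred sum of squares of y_j. This
identity (a) proves T_k ≥ 0, (b) shows T_k is invariant to allele flips
(g → 2 − g), to the (1,0)/(0,1) order of heterozygote expansion, and to
per-phenotype affine rescaling, and (c) is the package's primary correctness
oracle: the batched permutation path computes the right-hand side at the
individual level (c_j and v_j need only N-level sums), while the reference
implementation follows the weighted-combination definition on the 2N rows;
the two agree to ~1e-10 relative error in the test suite, and to machine
precision in exact arithmetic.

### Permutation procedure

T_k has no tractable null distribution, so inference is by permutation of
the genotype vector at the individual level (phenotypes, and hence the
clustering and phenotype correlation structure, stay fixed). With B
permutations and b = 0 denoting the observed data:

    p_k^(b) = #{d = 0..B : T_k^(d) > T_k^(b)} / B
    T_WCHC^(b) = min_k p_k^(b)
    p-value = #{b = 1..B : T_WCHC^(b) < T_WCHC^(0)} / B .

Weights are recomputed inside every permutation — they are functions of x,
and freezing them would break exchangeability and inflate type I error. The
strict inequalities and the denominator B are kept exactly as written, which
permits p = 0; an optional `add_one` flag switches the final p-value to the
(r + 1)/(B + 1) estimator for users who need a positive lower bound.
Counting strict `>` over d = 0..B means ties among permuted statistics
lower all tied p_k values together; with continuous phenotypes ties occur
with probability zero. WCmulP is the K = 1 special case (all phenotypes in
one cluster, no clustering step).

### Hierarchical clustering and the stopping rule

Phenotypes start as singletons and the pair of clusters with the largest
similarity merges at each iteration, where similarity is |Pearson r| for two
singletons, the multiple correlation coefficient when a singleton meets a
block (singleton as response), and the first canonical correlation between
two blocks. All three are computed exactly from the M × M phenotype
correlation matrix, which is mathematically identical to recomputing from
the raw columns at every iteration (there is no Lance–Williams update for
canonical correlation; the correlation-matrix form is simply the cheap way
to do the exact recomputation). Similarities are sign-blind by design: the
combination weights w_j carry the sign, so strongly negatively correlated
phenotypes should cluster together.

With merge heights h_1, …, h_{M−1}, the stopping iteration is
b̂ = argmin_{1≤b≤M−2} (h_{b+1} − h_b) — the largest drop in similarity —
and the partition is the cluster set existing after iteration b̂, so
K = M − b̂. Ties in the merge step break to the lexicographically smallest
pair of smallest member indices; ties in the argmin break to the smallest b
(more clusters). For M = 2 the rule is undefined and K = 1 is returned.
Heights need not be monotone and the rule does not assume they are. The
clustering is computed once from the observed phenotypes and held fixed
across permutations and variants.

## Comparator tests

* **O'Brien (OB)** — 1'Σ⁻¹T_uni standardised by (1'Σ⁻¹1)^½, two-sided
  normal p-value. Optimal under homogeneous effects; deliberately sensitive
  to effect direction.
* **SHet** — S_Hom(τ) = [1'(Corr W)⁻¹t]² / [1'(W Corr W)⁻¹1] restricted to
  {j : |t_j| > τ}; S_Het = max over a threshold grid (default: 0 plus the
  sorted observed |t_j|, W = identity). The Monte-Carlo p-value draws null t
  vectors from MVN(0, Corr) and pushes each through the same grid. The
  implementation exploits that the selected subsets are prefixes of each
  draw's own descending-|t| order: after permuting Corr into that order, one
  Cholesky factorisation plus two triangular solves yields every prefix
  statistic via cumulative sums, so all draws are evaluated in one batched
  linear-algebra pass (verified against a brute-force subset oracle).
* **TATES** — min_j M_e p_(j) / M_e(j) over the ascending per-phenotype
  p-values, with effective numbers of tests from the eigenvalues of the
  p-value correlation matrix (M_e = M − Σ_{λ>1}(λ − 1)). The p-value
  correlation is obtained from the phenotype correlation through the
  sixth-degree polynomial fit published with the TATES procedure
  (van der Sluis et al., 2013), applied to |r| because two-sided p-values
  are invariant to the correlation's sign. The procedure reduces exactly to
  Simes under identity correlation.
* **MANOVA** — multivariate regression of Y on dosage; with a single
  predictor Wilks' Λ = 1 − R² (R² the squared multiple correlation of g on
  Y) and Rao's F = (1 − Λ)/Λ · (N − M − 1)/M is exact on F(M, N − M − 1).
* **MultiPhen** — proportional-odds logistic regression of the dosage
  (ordinal response; absent levels collapse the cut-points) on the M
  phenotypes, likelihood-ratio statistic against the cut-points-only model
  referred to χ²_M. The fit uses statsmodels' ordinal model; the null
  log-likelihood is the closed-form multinomial value.
* **Univariate statistics** for OB/SHet/TATES are the per-phenotype
  simple-regression t statistics r√(N−2)/√(1−r²) treated as z-scores, with
  null correlation matrix estimated by the phenotype correlation matrix —
  the standard choice when the source method leaves T_uni unspecified.
  Perfect fits are capped at 1e8 rather than returned infinite.

## The simulator

Genotypes are Binomial(2, MAF) (Hardy–Weinberg), MAF = 0.3 by default.
Phenotypes follow y = λx + cγf + √(1 − c²)·ε with R exchangeably correlated
factors, f ~ MVN(0, (1 − ρ)I + ρ11'), block-diagonal all-ones loadings γ,
and independent standard-normal noise. Under the null every phenotype has
unit variance; phenotypes sharing a factor correlate at c², across factors
at ρc². Users parameterise by the target correlations (c², ρc²); the factor
correlation is recovered as ρ = ρc²/c². Six architectures set λ: equal
effects on all phenotypes (model 1), on one of two factors (2), graded
β(j/(M+1) + 1) on one of two factors (3), equal or graded effects on the
last of four factors (4, 5), and opposing-direction effects on the last two
of four factors (6). Default study conditions are N = 1,000, M = 16 or 32,
c² = 0.5, ρc² = 0.1; β = 0 gives the null used for type-I-error estimation.
Heritability per phenotype is var(x)λ_j²/(var(x)λ_j² + 1) with
var(x) = 2·MAF·(1 − MAF).

What the simulator does **not** emulate: linkage disequilibrium between
variants, population stratification or relatedness, non-normal phenotype
distributions, missing data, and binary traits. Passing calibration and
power tests therefore demonstrates correctness of the statistical machinery
under an idealised exchangeable-null design, not robustness to those
real-data complications (covariate adjustment and complete-case handling in
the I/O layer address the routine part of them only).

## Experiments and numerical choices

Type-I-error and power runs draw a fresh dataset per replicate, run each
requested method, and count rejections as p < α uniformly (p ≤ α differs
only on the permutation grid). Replicates get independent child seeds by
seed-sequence spawning, so results are independent of the worker count.
Rates carry exact Clopper–Pearson 95% intervals; the study-design
normal-approximation interval α ± 1.96√(α(1−α)/n) is exposed separately.

Problem sizes: the full-scale presets use 2,000 replicates × 2,000
permutations for null tables and 1,000 × 1,000 for power curves; the
packaged test suite runs the same pipelines at 500 × 500 (null calibration,
six methods × three factor settings) and 300 replicates (power ordering),
sizes at which the binomial Monte-Carlo error is still small relative to the
effects being checked. `scripts/acceptance.py` uses the full 2,000 × 2,000
scale.

Degenerate inputs are rejected, not repaired: monomorphic genotypes,
zero-variance phenotypes, and collinear phenotype blocks raise informative
errors; MultiPhen non-convergence returns NaN and is reported separately by
the experiment drivers rather than silently dropped.

## Known limitations

* The permutation p-value's resolution is 1/B; genome-wide thresholds
  require B ≫ 10⁷ or the staged screen-then-refine strategy.
* The clustering stopping rule always returns K ≥ 2 for M ≥ 3 when applied
  verbatim (b̂ ≤ M − 2); a truly one-cluster truth is still handled well
  because per-cluster tests remain valid, merely slightly less powerful
  than WCmulP.
* TATES' polynomial mapping is an approximation fitted for bivariate normal
  phenotypes; under strong non-normality its effective numbers drift.
* SHet's Monte-Carlo p-value has resolution 1/n_mc and treats the estimated
  phenotype correlation as the truth.
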