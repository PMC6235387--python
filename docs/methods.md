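# Methods

## The model

`famvar` analyses quantitative traits measured on members of many small,
mutually unrelated families. Within each family block the trait vector is
multivariate normal with mean `X β` (fixed covariate effects) and a
covariance assembled from three matrices: the additive relationship matrix
`2Φ` (twice the kinship coefficients), a household-sharing indicator `H`,
and the identity:

    Σ = 2Φ σ²_g + H σ²_c + I σ²_e            (ACE decomposition)

Narrow-sense heritability is `h² = σ²_g / (σ²_g + σ²_c + σ²_e)`. Because
families are independent, the log-likelihood is a sum over blocks, and all
fits scale linearly in the number of families.

Three extensions of this base model are implemented:

* **Sex limitation (genotype-by-sex interaction).** Genetic and unique
  environmental standard deviations become sex-specific (`σ_gM`, `σ_gF`,
  `σ_eM`, `σ_eF`) and genetic effects expressed in the two sexes are
  allowed an imperfect correlation `ρ_gMF ∈ [0, 1]`:
  `cov(M,M) = 2φ σ²_gM`, `cov(F,F) = 2φ σ²_gF`,
  `cov(M,F) = 2φ σ_gM σ_gF ρ_gMF`. Two nested constraints are tested:
  `ρ_gMF = 1` (same genes in both sexes; boundary constraint, 50:50
  point-mass/χ²₁ mixture null) and `σ_gM = σ_gF` (same magnitude; interior
  constraint, plain χ²₁ null).
* **Bivariate pleiotropy.** Two traits jointly, per-block covariance
  `2Φ ⊗ G + I ⊗ E` with 2×2 genetic and environmental matrices
  parameterised by variances and correlations `ρ_g`, `ρ_e`. The implied
  phenotypic correlation is
  `ρ_p = ρ_g √(h²₁ h²₂) + ρ_e √((1−h²₁)(1−h²₂))`. Zero-value tests of
  `ρ_g`, `ρ_e` and `ρ_p` refit under the constraint and use χ²₁; the `ρ_p`
  test is a nonlinear equality constraint (the formula value forced to 0),
  solved with an SLSQP refit started from the unconstrained optimum and
  from the both-correlations-zero projection.

## Kinship

Computed by the recursive tabular method over an ancestors-first ordering:
`φ(i,i) = ½(1 + φ(f_i, m_i))`, `φ(i,j) = ½(φ(f_i,j) + φ(m_i,j))`, with
founders non-inbred and mutually unrelated, and an unknown parent treated
as a unique unobserved founder (this preserves half-sib relationships).
Requesting a subset of individuals first closes over their ancestors, so a
submatrix is always identical to the corresponding slice of the full
matrix. The tests validate kinship against a gene-dropping Monte-Carlo
oracle (simulated allele transmission).

Blocks are connected components of the union of parent-child edges and
shared family id, which keeps both `2Φ` and the household matrix
block-diagonal even if a household contains genetically unrelated members.

## Estimation and numerics

* **Full maximum likelihood, not REML.** The workflow is model comparison
  by likelihood-ratio tests with the fixed-effect set held constant across
  compared models, for which ML log-likelihoods are the natural currency.
* **Profiled fixed effects.** For any variance-parameter value, the
  optimal `β` is the GLS solution, computed in closed form inside each
  likelihood evaluation; the outer optimiser therefore works only on the
  (2-6) variance parameters. This gives identical estimates to joint
  optimisation, faster and more robustly.
* **Bounded natural-scale optimisation.** Variances are optimised directly
  with L-BFGS-B under bound constraints (`σ² ≥ 0`, with a tiny positive
  floor on unique-environment variances to keep Σ positive definite;
  correlations inside their intervals, `ρ_gMF` on `[0, 1]` by default).
  Direct bounds were chosen over log/atanh transforms because boundary
  optima — `σ²_g = 0`, `ρ_gMF = 1` — are then attained *exactly*, which is
  what the boundary-mixture LRTs assume: under the null about half the
  fitted statistics are exactly zero rather than numerically small.
* **Deterministic multi-starts.** Up to three starts splitting the
  covariate-adjusted sample variance differently between components
  (environment-heavy, genetic-heavy, balanced); the best optimum is kept.
  Fits are deterministic given data.
* **Convergence** at `ftol = 1e-10` on the (profiled) log-likelihood;
  LRT statistics are clamped at zero so optimiser noise can never produce
  a negative statistic.
* **Non-positive-definite covariances** return `-inf` from the likelihood
  (a rejected step for the optimiser), never an exception.
* **Standard errors.** `h²` SE by the delta method on the inverse observed
  information of the profile likelihood in the variance parameters
  (central differences, with steps shrunk near the lower bounds).
* **Batched linear algebra.** Blocks of equal dimension are stacked and
  all Cholesky factorisations/solves are batched `numpy.linalg` calls, so
  a survey-scale evaluation (~1,100 families) costs a few hundred
  microseconds. Missing rows are dropped per block *after* kinship is
  computed on the full pedigree, so unphenotyped connecting relatives
  still shape the relationships among analysed members.

## Preparation choices

* Inverse normal transformation: Blom offset `c = 3/8`, average ranks for
  ties; missing values stay missing. This fixes the trait's marginal scale,
  so reported variance components are fractions of (near-)unit phenotypic
  variance.
* Exclusion cascade applied in a fixed order (overt dysfunction, prior
  treatment, pregnancy, TPOAb ≥ 34.0 IU/mL, missing TSH/fT4/urinary
  iodine, then families reduced below two members), each rule tallied. The
  euthyroid mode additionally requires no personal/family thyroid history
  and TSH ∈ [0.62, 6.86] mIU/L, fT4 ∈ [0.89, 1.76] ng/dL — closed
  intervals, boundary values retained.
* UICR = urinary iodine / urinary creatinine × 100 (µg iodine per g
  creatinine); non-positive creatinine yields a missing value. UICR enters
  models natural-log-transformed.
* Stepwise screen: forward/backward with `p_enter = p_remove = 0.10`
  (configurable), LRT p-values from χ²₁ computed inside the polygenic (AE)
  model, complete-case throughout so every candidate fit uses the same
  rows. Two candidate sets: basic `{age, age², sex}` and extended
  `{age, sex, BMI, smoking, log-UICR, menopause}` with males coded as not
  menopausal. Sex-stratified fits drop covariate columns that become
  constant in the subsample.

## The synthetic-data generator

The generator emulates a national-survey family sample: 1,115 families
drawn mostly as phenotyped pairs ({2: 0.98, 3: 0.02} surveyed members per
family, ≈2,250 surveyed individuals), composed half as sibships (founder
parents present in the pedigree but unsurveyed) and half as
parent-offspring/nuclear sets, with 53.4% of surveyed members male.
Latent traits are drawn per block from the *same* covariance equations the
fitters use (unit phenotypic variance per trait and sex), so generator and
likelihood agree by construction; covariate effects (age ~ U[10, 55] for
offspring / U[35, 80] for founders, sex, BMI ~ N(23.5, 3.2²)) are added as
fixed effects contributing about 5% of variance each; TSH is then mapped
through an exponential (median ≈ 1.4 mIU/L) and fT4 linearly into its
reference range, so the pipeline's rank-based transformation is exercised
non-trivially. Auxiliary columns (urinary iodine and creatinine, TPOAb,
smoking, menopause, exclusion flags) are generated with realistic marginal
distributions; a `contamination` option injects TPOAb-positive rows to
exercise the exclusion cascade.

Preset true parameters are literature-scale values: overall h² 0.54 (TSH)
and 0.56 (fT4); sex-specific TSH h² 0.41 (male) / 0.75 (female); female
bivariate truth ρ_g = −0.347, ρ_e = 0.367 with h² = (0.75, 0.52); null
presets set the tested effect to its null value.

What the generator does **not** emulate: survey sampling weights and the
multistage sampling design, assay measurement error, age-dependent
variance components, assortative mating, real household rosters (e.g.
spouse pairs beyond nuclear parents), or genotype data. Passing
recovery/calibration tests therefore demonstrates correctness of the
estimators under the stated model, not robustness to these features of
real survey data.

## Problem sizes used in validation

The test suite validates likelihoods against a dense multivariate-normal
oracle on random pedigrees of up to 8 members; parameter recovery uses 100
replicates at full survey scale (1,115 families); null calibration of the
genotype-by-sex tests uses 500 replicates of 300 families, a size at which
the boundary point mass and the interior rejection rate are already stable;
simulation-based screening and pleiotropy checks use 150-400 families per
replicate. These sizes were chosen so each property is measured with
Monte-Carlo error well inside its assertion band.

## Known limitations

* The C (household) component equals family-block membership; nested
  household structures within extended families are not modelled.
* `ρ_gMF` is only identified when phenotyped opposite-sex relative pairs
  exist; the fitter warns and the estimate rests at its starting bound
  otherwise.
* Delta-method SEs are unreliable when a variance estimate sits at zero;
  they are reported as computed, with non-finite values where the
  information matrix is singular.
* Power of the `σ_gM = σ_gF` test at the preset sex-specific truths
  (0.75 vs 0.41) and survey scale is moderate (~40-50% in simulation), so
  single datasets frequently fail to reject even under a real difference.
* No multiple-testing adjustment is applied; p-values are unadjusted and
  two-sided with α = 0.05, matching the analysis workflow the package
  reproduces.
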