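# Methods

`gxekit` implements two complementary strategies for detecting and
quantifying gene–environment interaction (G×E) for polygenic traits, built
around genome-wide SNP data rather than candidate genes.

## 1. Risk-profiling framework

### Model

A genomic risk profile score (GRPS) aggregates an individual's risk-allele
counts weighted by effect sizes estimated in an independent discovery GWAS:

    score_i = ( Σ_j x_ij β_j ) / n_i ,

where x_ij counts the effect allele, β_j is the discovery weight (log odds
ratio or regression coefficient) and n_i is the number of loci with a
non-missing genotype for individual i. For a binary outcome the interaction
test fits the nested logistic sequence

    {covariates} ⊂ {+E} ⊂ {+G} ⊂ {+G×E}

and compares consecutive maximised log-likelihoods by χ² likelihood-ratio
tests with degrees of freedom equal to the number of columns added; several
score partitions (e.g. by functional annotation) contribute one G and one
G×E column each. Nagelkerke R² increments are reported per term. A
significant G×E term speaks to interaction on the underlying liability
scale; significant main effects alone already imply interaction on the
observed disease scale, so the table reports each term separately and
leaves the scale interpretation to the analyst. Quantitative outcomes use
the analogous linear nesting with F-tests.

### Numerical choices

* Logistic maximum likelihood is delegated to statsmodels' Newton solver.
  Complete or quasi-complete separation (common in small simulated
  fixtures) triggers a Firth-penalised fallback (Jeffreys-prior penalty,
  Newton with step-halving, tolerance 1e-10, 100 iterations) with a
  warning; the unpenalised log-likelihood of the Firth solution enters the
  LRTs so nested statistics remain comparable.
* Score columns are z-standardised by default before the G and G×E columns
  are built. The LRTs are invariant to any affine rescaling of G or of a
  continuous E (the nested column spans are identical), so this choice
  affects only coefficient readability; a raw-score option is kept.
* Across-partition multiplicity: Bonferroni-adjusted G×E p-values are
  reported next to the raw ones; no other correction is imposed.
* Decile stratification ranks on the score with position-based tie
  breaking (stable mergesort), splits into ten near-equal groups (sizes
  differ by at most one) and reports the odds ratio of each decile against
  the bottom decile with Woolf (log-scale normal) 95% intervals. Zero cells
  flag the ratio as 0/∞ instead of erroring.
* Discovery/target overlap is the classic failure mode of profile scoring;
  `warn_on_sample_overlap` warns on any shared (FID, IID), and the
  simulator's discovery generator refuses overlapping ids outright.

## 2. Mixed-linear-model framework

### Model

    y = Xb + g + ge + ε,
    Var(y) = σ²_g A_g + σ²_ge A_ge + σ²_e I.

A_g is the SNP-derived genetic relationship matrix (GRM),

    A_jk = (1/m_jk) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2 p_i (1 − p_i)),

with in-sample allele frequencies and per-pair counts m_jk of loci observed
in both individuals. The interaction matrix encodes that interaction
effects are shared only within an environment: for binary or categorical
exposures A_ge[j,k] = A_g[j,k] when e_j = e_k and 0 otherwise (the diagonal
is always kept — an individual shares its own environment); for continuous
exposures the reaction-norm form A_ge = A_g ∘ zzᵀ with z the standardised
exposure. Variance components are estimated by restricted maximum
likelihood and tested by likelihood-ratio tests; the proportion of
phenotypic variance attributable to G×E is σ²_ge over the component total.

### REML implementation

* Average-information (AI) REML: score and AI matrix computed from P and
  Py; traces use the identity tr(PA) = Σ (P ∘ A) for symmetric A so each
  iteration costs a single Cholesky factorisation/inversion. The first
  step is a damped EM step; AI proposals that leave the feasible region or
  decrease the likelihood are step-halved, with an EM step as the
  guaranteed-ascent fallback.
* Components are constrained non-negative by active-set clamping at a
  floor of 1e-8 × Var(y); an unconstrained option is kept for LRT
  construction. Convergence: relative log-likelihood change < 1e-8; cap
  200 iterations (error with the iteration trace beyond that). Standard
  errors come from the inverse AI matrix at the optimum; variance
  proportions and their SEs by the delta method.
* Starting values: every component at Var(y)/(k+1). All tie-breaks are
  deterministic, so a fit is bit-reproducible for fixed input.
* The E main effect is always placed in X when A_ge is fitted: the
  random-effects decomposition omits fixed effects, but leaving the E mean
  out would let a group mean difference masquerade as interaction
  variance.
* Proportional relationship matrices (e.g. an identity supplied as a
  "genetic" matrix) are rejected up front as unidentifiable.
* Testing σ²_ge = 0 places the parameter on its boundary, so the default
  null reference is the ½χ²₀ + ½χ²₁ mixture; the plain χ²₁ reference is
  available by flag. The paired-fit LRT errors if the reduced model's
  log-likelihood exceeds the full model's beyond 1e-3 (a non-convergence
  indicator).
* Binary disease phenotypes are analysed on the observed 0/1 scale; no
  liability-scale transformation of the estimates is attempted, and for
  disease traits the bivariate r_g test below is the recommended
  significance test because the correlation is unaffected by
  per-environment ascertainment.

### Bivariate cross-environment model

With binary E the phenotype is treated as two traits, one per environment.
Individuals sit in exactly one environment, so the stacked covariance has
within-group blocks σ²_g,k A_kk + σ²_e,k I and cross-group block
r_g σ_g,1 σ_g,2 A_12, with no residual cross-covariance. The free fit uses
the linear parameterisation (σ²_g1, σ²_g2, c_g, σ²_e1, σ²_e2) — AI-REML
applies unchanged, c_g unconstrained in sign — and reports
r_g = c_g/√(σ²_g1 σ²_g2) with a delta-method SE (the free estimate may
exceed 1; the constrained fits respect |r_g| ≤ 1 by construction). The
r_g = 1 fit maximises over genetic standard deviations (s1, s2) with an
analytic REML gradient under L-BFGS-B; the r_g = 0 fit drops the cross
block. Both constrained fits are compared to the free fit by df = 1 LRTs;
r_g significantly below 1 is the G×E criterion. When per-environment
heritabilities differ, r_g = 1 does not by itself exclude G×E (a scale
effect is then the likely reading), so the per-group variance estimates are
reported alongside and `transform_phenotype` (rank-inverse-normal with Blom
offset, or log) supports before/after scale-effect checks. r_g is flagged
undefined when either genetic variance estimate is numerically zero.

## 3. Simulator

The generator draws unlinked Hardy–Weinberg genotypes (allele frequency
uniform in the configured MAF range, dosage = two Bernoulli draws),
standardises dosage columns, and builds

* g = Zβ with β ~ N(0, 1) rescaled so the realised sample variance equals
  σ²_g exactly;
* ge: for binary/categorical E an **independent** effect vector γ^(ℓ) is
  drawn per environment level and individual j receives Z_j γ^(e_j); this
  gives Cov(ge_j, ge_k) = σ²_ge A_jk for same-environment pairs and 0
  across environments — precisely the structure the masked A_ge encodes,
  so variance-component recovery experiments are internally consistent. A
  centred-product construction (Zγ)·f(e) with binary f was considered and
  rejected for the fitting surface: its implied covariance is
  σ²_ge (2 A_ge − A_g), which biases the masked-matrix fit by ±σ²_ge. The
  product form is retained for continuous E, where it matches A_g ∘ zzᵀ.
  An "amplification" mode (interaction effects proportional to the main
  effects in the exposed group) generates pure scale effects for
  transformation experiments.
* ε Gaussian; each realised component rescaled to its configured variance
  exactly, so recovery experiments measure estimation error only.

Binary traits threshold the liability at √(σ²_tot)·Φ⁻¹(1 − K) for
prevalence K; optional case-control ascertainment keeps all cases and thins
controls to a target case fraction. The discovery generator simulates an
independent cohort at the same allele frequencies with the same allelic
effects (its own environment draw) and returns per-variant marginal OLS
coefficients as summary statistics.

What the simulator does **not** emulate: linkage disequilibrium (variants
are independent, so GRM off-diagonals are purely sampling noise),
population structure, dominance/epistasis, genotyping error or
missingness mechanisms beyond missing-completely-at-random. Passing tests
therefore demonstrate correctness of the estimators under the assumed
model, not robustness to the confounders of real cohorts.

## 4. Verification sizes

Monte-Carlo problem sizes used by the test suite and `scripts/acceptance.py`
(chosen for a single-CPU run; the per-replicate information about a
variance component scales like n/√m, so smaller cohorts with fewer SNPs
retain comparable precision per replicate):

* REML oracle agreement: 5 fixtures, n = 200, two relationship matrices;
  AI optimum vs dense grid + Nelder–Mead refinement (tolerance 1e-4) and
  likelihood values vs explicit determinant/inverse algebra (1e-8).
* Parameter recovery: n = 1200, m = 2000, (σ²_g, σ²_ge, σ²_e) =
  (0.3, 0.2, 0.5), binary E at prevalence ½, 15 replicates; max mean
  absolute bias ≤ 0.05.
* Type-I error: profiling LRT at n = 2000 × 1000 replicates; REML mixture
  LRT at n = 500, m = 800 × 600 replicates; both gated to [0.035, 0.065]
  at α = 0.05.
* Bivariate discrimination: n = 450 per environment, m = 400, 20
  replicates per scenario (shared vs environment-specific effects).
* Scoring pipeline: discovery n = 5000 → target n = 1000, m = 300,
  σ²_g = 0.5, 20 replicates; the genetic term must be detected in ≥ 80%.

## Known limitations

* Dense-matrix REML: memory and time scale as n² and n³; cohorts beyond a
  few tens of thousands need the streaming/partitioned tricks of dedicated
  GREML software.
* The observed-scale analysis of binary traits means per-environment
  variance proportions for diseases are descriptive only.
* The categorical-E masking rule generalises the binary rule (same level →
  A_g, else 0); exposures with many sparse levels will leave A_ge close to
  block-diagonal noise and the component weakly identified.
* Firth fallback SEs are Wald-type from the penalised information; for
  tiny separated fixtures, profile-likelihood intervals would be better.
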