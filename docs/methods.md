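# Methods

## Model

The package targets binary-trait association in samples with population
structure and cryptic relatedness.  The generative model is a mixed logistic
regression (MLR),

    logit E(y) = X β + G γ + ω,      ω ~ MVN(0, τ K),

with `y ∈ {0,1}ⁿ`, `X` an n×p covariate matrix containing an intercept, `G`
a dosage vector (0/1/2 alt-allele counts), and `K` an n×n relatedness
matrix — either the empirical genomic relationship matrix (GRM) or twice the
pedigree kinship matrix.  The exact likelihood integrates over ω and has no
closed form; everything here works in the penalized quasi-likelihood (PQL)
approximation.

## Null-model fit (PQL)

`fit_pql_null` alternates two steps until the maximum absolute change in
(β, τ) falls below `tol` (default 1e-6, max 200 outer iterations):

1. working linearization: with the current η = Xβ + ω, set
   μ = logistic(η), W = diag(μ(1−μ)), z = η + W⁻¹(y − μ);
2. one REML update of the working linear mixed model
   z = Xβ + ω + e, ω ~ N(0, τK), e ~ N(0, W⁻¹): β and ω by GLS/BLUP given
   τ, and τ by a single safeguarded Newton step on the REML log-likelihood
   using the exact gradient and the average-information curvature, with a
   trust region of 2(τ + 0.1) and τ constrained to [0, 50].

Numerical choices: fitted probabilities are clipped to [1e-8, 1−1e-8]
before forming W; Σ = τK + W⁻¹ is factored by Cholesky (never an explicit
inverse); `tr(Σ⁻¹K)` is evaluated from diag(Σ⁻¹) via a triangular inverse
when τ > 0 and as `tr(WK)` at the τ = 0 boundary.  Initialization is plain
logistic IRLS for β, τ = 0.1, ω = 0; warm starts (`beta0`, `tau0`) are
accepted and used by the experiment harnesses.  A linear predictor
exceeding 35 in absolute value raises a convergence error — with clipped
probabilities, complete separation would otherwise stall silently.

The scalar-τ Newton update was chosen over a nested 1-D profile-REML search
because it costs one extra triangular inversion per outer iteration (same
O(n³) class, smaller constant) and, interleaved with the PQL linearization,
converges jointly with β; the τ = 0 boundary is handled by the gradient
sign rather than a barrier.

Known behavior, deliberately not "fixed": for Bernoulli data the PQL
variance component is attenuated — with one observation per individual and
moderate prevalence, τ̂ is substantially below the generating τ (the
sibship recovery test freezes the measured range, τ̂ ≈ 0.36 on average for
τ = 1).  Attenuation barely affects the fitted μ̂₀ and the per-variant
tests, which is what the toolkit is for; τ̂ itself should not be read as an
unbiased heritability-scale estimate.

## Per-variant tests

All fast tests reuse the converged null quantities: μ̂₀, η̂₀,
Σ = τ̂K + W⁻¹ and the projection P = Σ⁻¹ − Σ⁻¹X(X'Σ⁻¹X)⁻¹X'Σ⁻¹.

**AMLE.**  In the working model the log-likelihood in γ at the null has
first derivative U = G'(y − μ̂₀) and curvature −G'PG, so the second-order
expansion maximizes at γ̂ = U / (G'PG) with variance 1/(G'PG).  The Wald
statistic γ̂²/se² equals U²/(G'PG) — identically the mixed-model score
statistic; the package asserts this identity to 1e-12.  Cost per variant:
one P·G product, O(n²).  γ̂ is a genuine log-odds-ratio estimate but only a
first-order one: it under-shoots for large |γ| (see the bias experiments).

**Offset.**  The genotype is residualized on the covariates (G̃ = G − Xδ̂,
δ̂ by least squares) and γ is fitted by a one-parameter logistic IRLS of y
on G̃ with η̂₀ held as a fixed offset — no free intercept, since the offset
already carries Xβ̂₀.  Cost per variant: O(n) per IRLS iteration (50
iterations max, step tolerance 1e-10).  The final regression uses the
residualized G̃ rather than raw G: that choice makes the identity-link
analogue of the two-step procedure reproduce the multiple-regression OLS
coefficient exactly, which is the property that justifies the heuristic.

**Comparators.**  `lr_test` is plain logistic regression (no random
effect); `mlm_score_test` is the score test of the linear mixed model
fitted to the 0/1 status by REML (variance ratio profiled on the spectrum
of K).  The MLM is deliberately misspecified — its residual variance
μ(1−μ) differs between strata when prevalence does — and the package
reproduces the resulting category-dependent miscalibration.

The genome-scan driver vectorizes both fast tests (P·G as one matrix
product; all offset IRLS chains advanced simultaneously, each variant
frozen once its step is below tolerance) and never performs O(n³) work
inside the per-variant loop.  Per-variant failures are recorded in a status
column, never fatal.  P is stored dense; the intended regime is n up to
~10⁴.

## Stratified QQ diagnostics

With a stratifying variable Z ∈ [0,1]ⁿ, per-variant pseudo-frequencies are
q₁ = Z'G/(2Z'1) and q₀ = (1−Z)'G/(2(1−Z)'1); assuming within-stratum
panmixia the genotype variances are 2qᵢ(1−qᵢ) and variants are classified
by r = var₁/var₀ against a threshold th (default 0.8): category 1 if
r < th, 2 if th ≤ r ≤ 1/th (boundaries inclusive), 3 if r > 1/th.  A
variant monomorphic in stratum 0 but not 1 goes to category 3 (all its
variance sits in the high-risk stratum), and symmetrically; monomorphic in
both is excluded (category 0).  When strata are unknown, a top genomic PC
min-max rescaled to [0,1] serves as Z; on a strongly two-cluster cohort the
PC-based categories agree with the true-strata categories for ≥ 80% of
variants (a package-level proxy for "similar diagnostics" — no quantitative
criterion exists in the literature for this agreement).

The genomic inflation factor λ is median-based genomic control: observed
p-values are mapped back to χ²(1) quantiles and their median is divided by
0.45494 (the χ²(1) median).

## Synthetic cohorts

`simulate_grid_genotypes` replaces a coalescent stepping-stone run with a
seedable spatial Balding–Nichols model: ancestral frequencies uniform(0.05,
0.95); per-cell frequencies perturbed by a Gaussian field with exponential
spatial correlation (length 8 cells on a 20×20 grid, scaled down
proportionally for smaller grids) and per-cell variance
`structure_param · p(1−p)` with `structure_param = 0.04`.  This calibration
gives a half-grid F_ST ≈ 0.007 (< 0.01, comparable to intra-European
differentiation) and, on the 800-sample cohort below, SNP-category shares
of roughly 14/76/10% — close to the 11–24% / 59–78% / 11–17% range seen in
real and coalescent panels of this kind.  What the generator does *not*
emulate: linkage disequilibrium (variants are independent), allele-frequency
spectra skewed toward rare variants, genotyping error and missingness
patterns.  Calibration and power results on these cohorts therefore speak
to the structure/relatedness mechanism, not to LD-dependent phenomena.

`gene_drop` pairs founders into disjoint within-cell couples and draws each
offspring allele uniformly from the parent's two (transmission probability
d/2 for parental dosage d), giving exact first-degree relationships;
pedigree kinship is Φ with 0.5 diagonal, 0.25 parent-offspring and
full-sib, and K = 2Φ.  The default desk-scale cohort mirrors the full
design at 1/10 scale: a 10×10 grid, 10 founders per cell, 5 couples per
cell with 2 offspring each (2000 individuals), a uniform sample of n = 800,
and the top-left grid quarter as the high-risk stratum.

Phenotypes follow logit(pᵢ) = a₀ + a₁zᵢ + γ(gᵢ − ḡ) + ωᵢ with
ω ~ MVN(0, τK) drawn through a symmetric eigen-factorization of K
(eigenvalue floor 0; matrices with eigenvalues below −1e-8 are rejected).
The causal genotype is centered so the expected stratum prevalences stay at
(p₀, p₁).

## Experiments and problem sizes

The three harnesses redraw the phenotype each replicate and funnel all
randomness through one seeded generator; identical seeds give identical
tables.  Covariates in every analysis are an intercept plus the top 10
genotype PCs — the stratum indicator is never included, since handling
unobserved strata is the point.  Harness fits use a PQL tolerance of 1e-4
(γ̂ changes at that tolerance are orders of magnitude below Monte-Carlo
noise) and warm-start τ from the previous replicate.

* **Type-I**: tau = 1, prevalences 0.05/0.30, γ = 0; every cohort variant
  is scanned per replicate and rejection rates at α are tabulated per SNP
  category with normal-approximation binomial bands.  Five pooled
  replicates of 2000 variants are enough because the replicate-to-replicate
  variation of the conditional level was measured to be negligible next to
  binomial noise.
* **Power**: the causal variant is redrawn from a MAF bin each replicate
  and tested at α = 5×10⁻⁸.  The full-scale published design (n = 5000,
  1000 replicates) takes hours on one core; the default check is the
  reduced ordering version (n = 1000, 100 replicates, AMLE ≥ Offset within
  MC error), with full-scale parameters available through the same
  function.
* **Bias**: scenarios A (p₀=0.10, p₁=0.20, τ=0.3), B (same prevalences,
  τ=1), C (p₀=0.05, p₁=0.30, τ=0.3) × MAF bins (0.05;0.10], (0.20;0.25],
  (0.45;0.50] × 100 replicates, reporting mean(γ̂ − γ) and its MC standard
  error per method.  The bias cohort draws random effects from the
  empirical GRM (`pheno_kinship="grm"`), matching the protocol where real
  genotypes are the simulation substrate; type-I and power cohorts use the
  pedigree K = 2Φ for the phenotype while analyses use the SNP-derived GRM
  — a deliberate mismatch mirroring practice.

Expected patterns, all recomputed by the test suite and
`scripts/acceptance.py` rather than asserted from memory: MLR with 10 PCs
calibrated in all categories while MLM inflates category 3 and deflates
category 1; AMLE and Offset biased toward zero by at most ~0.08 at
γ = log 1.5 and ~0.1 (AMLE) at γ = log 2, with the full PQL refit
essentially unbiased; AMLE at least as powerful as Offset on the related
cohort (the offset method is conservative under strong familial structure).

## Limitations

Dense n×n linear algebra throughout: fits are O(n³) and P is materialized,
so the practical ceiling is n ≈ 10⁴.  No saddle-point correction: score
and AMLE p-values are anti-conservative for rare variants under heavily
unbalanced case-control ratios.  Single random effect only (one K); no
LOCO scheme; no meta-analysis utilities.  X and autosomes are treated
alike (no dosage-compensation conventions).
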