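# Methods

## Model

For each pedigree with n members and a T-variate trait Y (n × T), the model
is a multivariate normal on the vectorized trait,

    vec(Y) ~ N(Aβ, Σ),
    Σ = 2Σₐ ⊗ Φ + Σ_d ⊗ Δ₇ + Σ_h ⊗ H + Σ_e ⊗ I,

with **trait-major** vec ordering: the cell for trait t of individual i sits
at position t·n + i, so entry ((t, i), (t′, j)) of Σ is 2Σₐ[t,t′]Φ[i,j] + ….
This ordering is fixed everywhere — Kronecker assembly, design rows, score
caches — and is part of the package's on-disk conventions.

Components:

* **Φ (kinship)** — additive polygenic covariance. Theoretical Φ is computed
  by the standard recursion in parents-before-children order (founders:
  φ_ii = 1/2, φ between distinct founders = 0; child k of (f, m):
  φ_kk = (1 + φ_fm)/2, φ_kj = (φ_fj + φ_mj)/2). Founders are assumed
  non-inbred and mutually unrelated. SNP-based alternatives: the GRM
  Φ̂_ij = mean_s (x_is − 2p̂_s)(x_js − 2p̂_s)/(4p̂_s(1 − p̂_s)) and the
  method-of-moments matching estimator
  φ̂_ij = (e_ij − c_ij)/(S′_ij − c_ij) with
  e_ij = ¼Σ_s[x_is x_js + (2 − x_is)(2 − x_js)] and c_ij = Σ_s(p̂_s² + q̂_s²),
  both over pairwise-complete SNPs with monomorphic SNPs skipped, and
  optionally masked to zero between pedigrees. Per-SNP standardization is
  used for the GRM (rather than a pooled denominator); allele frequencies
  come from all individuals. Both estimators inherit an O(1/n_founders)
  bias from estimating p̂ on the analyzed sample itself; convergence tests
  therefore use designs with many founders.
* **Δ₇ (dominance)** — for non-inbred i (parents a, b) and j (parents c, d):
  Δ₇(i,j) = φ_ac·φ_bd + φ_ad·φ_bc, diagonal 1, founder off-diagonals 0.
  The non-inbreeding precondition is *checked* (every non-founder's parents
  must have φ = 0), not assumed; inbred pedigrees raise an error because the
  general Jacquard recursion is deliberately out of scope.
* **H (household)** — h_ij = 1 if i and j share a household ID, else 0;
  diagonal 1; individuals without an ID form singleton households.
* **I (environment)** — always active; Σ_e must be positive definite.

The mean Aβ supports intercepts, covariates and pairwise interactions, each
with one coefficient per trait unless an equality-constraint group ties a
set of (term, trait) cells to a single coefficient — the construction used
to share a covariate effect across longitudinal time points. Constraints
are implemented by column aggregation: a group's design column is the sum
of its member cells' columns, which reduces the free coefficients by
Σ(group size − 1) exactly.

## Missing data

Likelihood-exact treatment throughout: a missing trait entry deletes its
row/column of vec(Y), A and Σ (marginalization of the multivariate normal);
an individual missing any model covariate is dropped from the analysis and
logged; missing genotypes never enter kinship estimation (pairwise-complete
SNPs) and are mean-imputed to 2p̂ only inside association tests, where it
keeps each SNP's score evaluation a single vector product at a small,
documented power cost.

## Fitting

The loglikelihood per pedigree is
L = −½ ln det Σ − ½ (vec(Y) − Aβ)ᵀ Σ⁻¹ (vec(Y) − Aβ) − (m/2) ln 2π, summed
over pedigrees (m = observed cells). **The ln 2π constant is included** so
values are directly comparable with any generic multivariate-normal
density; conventions that drop it differ by exactly Σm/2·ln 2π.

Maximization: each active T×T component is parametrized by its Cholesky
factor (automatically PSD; Σ_e kept PD by the search staying off the
boundary), β is profiled out by GLS at every variance iterate, and the
profiled negative loglikelihood is minimized by L-BFGS-B with an analytic
gradient (envelope theorem: with β at its GLS optimum, only the partial
derivative in the variance parameters survives). Convergence: relative
loglikelihood change below 1e-8 and parameter change below 1e-6 (enforced
via ftol/gtol); the accepted-iterate trace is monotone and returned with
the fit. Components estimated at the boundary (trace ≈ 0) are flagged, not
errors. Initialization is deterministic and seed-free: Σ_e from the OLS
residual covariance (pairwise-complete), Σₐ at half of it, other components
at 0.05 × its diagonal.

Degenerate designs are detected: a rank-deficient design after constraint
collapsing is an error, and when Φ = I/2 for every analyzed block
(unrelateds) the additive and environmental components are linearly
confounded — the fitter emits a warning and sets a non-identifiability flag
rather than returning silently.

Empirical kinship matrices are eigenvalue-clipped to the PSD cone before
entering Σ, because method-of-moments estimates can be indefinite.

Standard errors: cov(β̂) = (AᵀΣ̂⁻¹A)⁻¹ from the GLS cache; the joint
asymptotic covariance of (β, vech Σₐ, vech Σ_e, …) comes from a central
finite-difference observed information at the MLE (`estimate_covariance`),
pseudo-inverted for boundary safety.

## Association testing

Score test: the SNP's T design columns are Xs = I_T ⊗ g (dosage g in each
trait's slot). With the variance parameters held at the null MLE,
U = XsᵀΣ̂⁻¹r, V = XsᵀPXs with P = Σ̂⁻¹ − Σ̂⁻¹A(AᵀΣ̂⁻¹A)⁻¹AᵀΣ̂⁻¹, and
S = UᵀV⁻¹U ~ χ²_T under the null. Everything SNP-independent is cached at
the null fit, so a whole scan is a handful of matrix products per pedigree
(`score_test_batch`). Constant dosages (after imputation) have singular V
and are flagged as undefined rather than tested.

LRT refinement: the top-k SNPs by score p (default 10, ties broken by
genome order) are re-tested by adding the T coefficients and re-maximizing
*everything*, warm-started at the null components; Λ = 2(L₁ − L₀) ≥ 0 up to
1e-6, p from χ²_T, with per-trait effect estimates reported. Non-converged
refinements keep the score result with a flag.

Scan-level diagnostics: λ_GC = median(S)/median(χ²_T) over score statistics
(not LRT values — it is a whole-scan diagnostic); Bonferroni threshold α/m
over the m SNPs actually tested, reported with its −log₁₀ to two decimals;
Benjamini-Hochberg step-up cutoff (plain BH — no dependence adjustment).

## Quality control

Fixed order, because survivor counts depend on it: (1) drop SNPs with call
rate below the SNP threshold (strict <, default 0.98); (2) drop individuals
with call rate below the individual threshold *computed on surviving SNPs*;
(3) apply the MAF rule over retained individuals — threshold and comparator
are configurable (strict `< 0.03` for family-style analyses, inclusive
`<= 0.01` for dense-cohort analyses) and the action is "flag" by default
(excluded from testing, retained for kinship) or "drop"; (4) compute the
founder-genotype Hardy-Weinberg exact p for reporting (report-only by
default: an extreme HWE p signals possible genotyping error and is
surfaced, not silently removed; a hard threshold is available). MAF can be
computed on any designated subset, since founder MAF and full-sample MAF
legitimately straddle a threshold.

The HWE exact test conditions on the allele counts and sums the
probabilities of all heterozygote counts no more probable than the observed
one; the distribution is evaluated in log space through the ratio
recurrence p(h+2)/p(h) = (m−h)(2n−m−h)/((h+2)(h+1)). It matches exact
integer-arithmetic enumeration to better than 1e-12 relative for all
configurations with total ≤ 200 (swept exhaustively in the test suite).

## Simulator

`simulate` generates the study conditions end to end from one seed,
consuming a single random stream in the fixed order pedigree → genotypes →
traits. Pedigrees are non-inbred by construction: founder couples, children
who marry unrelated founders, uniform sibship sizes, nuclear-family
households. Genotypes are gene-dropped: founder alleles i.i.d.
Bernoulli(MAF), one uniformly chosen allele per parent per locus,
independent loci (no linkage disequilibrium — a stated non-goal). Traits
are drawn from exactly the model covariance, with causal SNPs entering the
mean (matching how SNPs are tested); a planted SNP with per-allele shift β
contributes 2·maf(1−maf)·β² of trait variance, the bookkeeping used by the
power studies.

Defaults mirror a blood-pressure family study: 20 extended pedigrees,
bivariate (SBP, DBP)-like traits with Σₐ = [[43.15, 17.03], [17.03, 12.07]],
Σ_e = [[294.88, 113.90], [113.90, 102.61]] (units: mmHg²), sex effects
(10.90, 4.62) mmHg, age effects (0.43, −0.13) mmHg/yr, age ~ N(45, 12²),
and SNP MAFs uniform on [0.05, 0.5].

What the simulator does **not** emulate: linkage disequilibrium,
ascertainment, longitudinal autocorrelation beyond Σ_e ⊗ I, genotyping
error, population structure. Passing tests therefore demonstrate
correctness of the model, estimators and tests under the model's own
assumptions — not robustness to real-data violations of them.

## Validation study sizes

Chosen once as the package's standard validation conditions:

* null calibration: 2,000 score tests = 25 trait replicates × 80
  gene-dropped SNPs, bivariate trait, 20 pedigrees of ~26; empirical size
  at α = 0.05 within 3 binomial SEs, KS uniformity p > 0.01,
  λ_GC ∈ [0.95, 1.05];
* power: planted SNP at MAF 0.03 in ~850 members (33 pedigrees), scanned
  against 100 SNPs at the scan's Bonferroni level, 16 replicates per point
  of a {1%, 2%, 4%}-per-trait variance sweep bracketing the ~2% nominal
  effect; rejection strictly increasing, ≥ 0.8 at the largest effect;
* score/LRT equivalence: causal SNPs with score p < 1e-3; p-values within a
  factor of 2 and the pipeline LRT within 1e-4 of an independent
  from-scratch refit;
* parameter recovery: 100 replicates of 40 pedigrees (~1,040 individuals);
  each of the 12 parameters inside its asymptotic 95% interval ≥ 90% of the
  time;
* empirical kinship: 20 three-generation pedigrees (~340 individuals),
  RMSE against theoretical Φ decreasing over 10³/10⁴/5·10⁴ SNPs, GRM RMSE
  < 0.02 at 5·10⁴;
* kinship Monte Carlo: 10⁵ labelled gene drops, agreement within 3 SEs;
  Hardy-Weinberg: exhaustive sweep to total 200.

## Numerical choices and edge cases

* Dosages are re-oriented to minor-allele counts at load time (sample
  frequency; ties keep the coded allele); association tests are invariant
  to the 2 − x flip, but MAF reporting needs the convention.
* Tie handling in the HWE test uses a 1e-12 relative tolerance so exactly
  tied probabilities are not split by floating rounding.
* LRT statistics in [−1e-6, 0] are clipped to 0; anything more negative is
  an internal error, not clipped.
* Per-pedigree covariances are Cholesky-factored; a non-PD assembly names
  the offending pedigree in its error.
* bp positions are 1-based; SNP IDs follow the `chr-basepair` convention.
* Scan TSVs print floats at %.17g and are read back with round-trip float
  parsing, so write → read is bit-exact.

## Known limitations

X-linked loci, robust (t-distribution) likelihoods, REML, exact
finite-sample score distributions, saddlepoint corrections, multi-SNP
conditional models, rare-variant set tests and pedigree reconstruction are
out of scope. The Wald intervals on variance components rely on asymptotic
normality and can undercover near the PSD boundary; the parameter-recovery
study quantifies this under the default conditions.
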