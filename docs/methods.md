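# Methods

`bimr` implements a bidirectional Mendelian randomization (MR) analysis of
serum uric acid (SUA) and adiposity, together with a synthetic cohort
generator whose statistical structure matches what the analysis assumes.
This note records the model, the defaults and why they were chosen, the
numerical conventions, and what the simulations do and do not demonstrate.

## The estimand and the estimators

For a standardized exposure X and outcome Y, the causal parameter is the
per-SD effect β in Y = βX + confounding + noise. Genetic instruments Z
(randomly assorted at conception) identify β when they (i) associate with X,
(ii) are independent of confounders, and (iii) affect Y only through X.

Two-stage least squares (2SLS) regresses X on Z (first stage), then Y on the
fitted values X̂ (second stage); the coefficient on X̂ is the causal
estimate. In the just-identified single-instrument case this equals the Wald
ratio cov(Z,Y)/cov(Z,X) exactly — the test suite asserts that identity to
1e−10 rather than treating the two as independent methods. Standard errors
follow the IV convention: residuals are evaluated at the 2SLS coefficients
with the *observed* exposure (σ̂² = Σ(y − Xβ̂)²/(n−p)), and the covariance is
σ̂²(X̂ᵀX̂)⁻¹. The naive second-stage OLS residuals would understate the
uncertainty. Classical homoskedastic errors and ±1.959964·SE intervals are
used throughout; no robust or clustered variants are offered, matching the
conventions of cohort-era MR analyses.

Adjusted models place the exogenous covariates (age, sex, smoking, alcohol,
eGFR, diuretic use, plus any ancestry principal-component columns found in
the phenotype table) in **both** stages, the standard treatment of included
exogenous regressors in 2SLS.

Endogeneity is tested with the Durbin–Wu–Hausman procedure. The primary
form is the control-function regression — add the first-stage residual to
the OLS outcome model and t-test its coefficient — because it is defined for
every dataset. The contrast form (β_IV − β_OLS)²/(Var_IV − Var_OLS) against
χ²₁ is attached only when the variance difference is positive; when the
2SLS fit itself is impossible (first-stage F below the hard floor) the
augmented form is still returned with a note.

## Instruments

Instrument strength is summarized by the first-stage F, with the usual
F > 10 adequacy threshold; estimates from weaker instruments are flagged,
not suppressed, because sex-stratified analyses legitimately operate near
that boundary. A hard floor of F ≥ 1 guards the 2SLS ratio against
essentially signal-free instruments.

Single SNPs instrument SUA (urate transporter gene *SLC2A9*); an unweighted
additive allele score over k SNPs (default k = 3, configurable, k = 4
supported) from the adiposity genes *FTO*, *MC4R* and *TMEM18* instruments
the adiposity traits. Each SNP is first oriented so the counted allele
associates with higher values of the target trait — the operational,
in-sample definition of a risk allele. The best combination is found by
exhaustive enumeration of all C(m, k) candidate subsets, pooled across genes
with no per-gene quota, maximizing the crude first-stage F with a
deterministic lexicographic tie-break. Selection is repeated within each
stratum. Because orientation and selection use the analysis sample, the
procedure carries a known over-fitting (winner's curse) risk: the selected
instrument's in-sample F is upward-biased and the corresponding 2SLS
estimate is shrunk toward zero. This is deliberate — it reproduces the
published procedure — and is visible in the simulations.

The 0–6 score enters the first stage as a single linear regressor. The
collapsed version (categories 0–2 merged, kept ordered) exists only for
descriptive trend displays via Cuzick's (1985) Wilcoxon-type trend test
(tie-corrected, two-sided normal reference); 2SLS never sees it.

Instrument validity is screened, not proven: each instrument is regressed
against the measured covariates (continuous: linear slope and F-test;
categorical: chi-square over score levels) and the report flags small
p-values without an automatic verdict.

## Quality control

Marker and sample QC follow chip-era conventions with strict "less than"
boundaries: samples with genotype call rate < 95% are removed first; then
SNPs that are monomorphic, have call rate < 70%, minor allele frequency
< 1%, or violate Hardy–Weinberg proportions are excluded. The HWE test is
the 1-df chi-square goodness-of-fit at the sample allele frequency
(monomorphic markers return p = 1 and are left to the MAF filter); the
rejection level defaults to 1e−4, the conventional GWAS-QC choice, and is
configurable, as is an exact-test hook should one ever be needed at small n.

Two caveats are worth recording. First, the per-sample filter emulates a
chip-wide computation, but here it runs over the handful of simulated
markers, so per-SNP call rates must be high (the default scenario uses
0.985–0.995) for the filter to behave sensibly. Second, single-pass QC is
order-dependent by construction, and even iterating to a fixed point does
not make it order-independent when a low-call-rate SNP interacts with the
sample filter: removing its missing-call samples first lifts its recomputed
call rate to 1.0 and it survives, whereas removing the SNP first keeps the
samples. The package documents and defaults to samples-first single-pass;
`qc_cohort(iterate=True)` is available and order-independence holds for
defect patterns that do not couple the two filters.

eGFR is derived with the abbreviated MDRD equation,
186 × (creatinine/88.4)^−1.154 × age^−0.203 × 0.742^[female], in
ml/min/1.73 m², from serum creatinine in µmol/L.

## Trait transformations

Fixed variance-stabilizing transforms precede analysis: log for weight and
waist, square root for SUA and fat mass, inverse square root for BMI. The
BMI transform is **negated** (−1/√BMI) so that the transformed value
increases with BMI; otherwise the sign of every SUA–BMI coefficient would
flip relative to the other traits. Transformed variables are standardized
with the sample (n−1) SD **within each analysis's complete-case sample**, so
each reported per-SD effect is scaled by exactly the sample it was estimated
in. Complete-case selection requires non-missingness on the outcome, the
exposure, every instrument SNP, and (for adjusted models) every covariate,
which is why n varies slightly across rows.

## The synthetic cohort generator

Genotypes are independent biallelic SNPs drawn from Hardy–Weinberg
trinomials, optionally deformed by Wright's inbreeding coefficient F
(P(het) = 2pq(1−F)) to create HWE-violating markers, with missing calls
injected at 1 − call_rate. No linkage disequilibrium is simulated: the
score treats SNPs additively and the analysis never exploits LD.

Latent structure: a single standard-normal confounder U, a latent
standardized adiposity factor A, and latent standardized (transformed) SUA
S. Each trait loads on its own instrument in every scenario — the adiposity
score with coefficient α_A = √(R²_adip/Var(score)) and the *SLC2A9*-like
SNP with α_S = √(R²_SUA/Var(g)) — because a cohort always carries both
genetic signals; the `direction` parameter only switches which causal path
between A and S is active (`adiposity_to_sua`, `sua_to_adiposity`, `null`,
or reciprocal `both`). Residual SDs are solved so every latent trait has
population variance exactly 1; an infeasible budget (loadings explaining ≥ 1)
raises an error naming the offending trait. In the reciprocal case the
reduced form of the simultaneous system is rescaled to unit variance, so
the structural β there refers to the pre-scaling equations.
`population_moments()` returns the exact implied covariances and
large-sample OLS slopes — e.g. the confounded slope β + c_A·c_S — which the
recovery tests use as the predicted-bias oracle instead of re-deriving it.

Default calibration: the score explains R² = 0.0070 of the latent adiposity
factor and the SUA SNP R² = 0.0316 of latent SUA — the strong-urate-gene /
weak-adiposity-score regime this study design lives in. The four observed
adiposity traits load on A with loadings (waist 1.0, weight 0.926, BMI and
fat mass 0.862) chosen so the per-trait instrument R² spreads over
0.0052–0.0070, matching the published spread across traits. Default
confounder loadings are 0.45 on each trait (OLS bias +0.2025 per SD), the
default causal effect is β = 0.30 from adiposity to SUA, and candidate MAFs
sit in 0.22–0.43.

Covariates are noisy functions of U — age (r = 0.2), smoking and alcohol
(logistic in U), diuretic use (logistic in U and age), creatinine
(r = 0.3, sex-specific base) — so adjusting for them removes only part of
the confounding and crude vs adjusted analyses genuinely differ. Sex is
independent of U and of genotype.

Raw-scale output inverts the analysis transforms around sex-specific
location/scale constants (e.g. weight = exp(4.40 + 0.163·z) kg for men),
picked to give means and SDs of the order seen in middle-aged European
cohorts: men heavier and with SUA ≈ 90 µmol/L higher, women with higher fat
mass. Because the inverse transforms are exact inverses of the analysis
transforms, the pipeline recovers the latent traits up to an affine map and
no calibration is lost — with one instructive exception: sex-specific
locations add between-sex variance in the overall sample, so the realized
overall-sample instrument R² is diluted below its latent target (e.g. the
SUA SNP's 0.0316 appears as ≈ 0.018 overall), exactly as demographic
structure dilutes instrument strength in real cohorts. Calibration targets
are therefore verified on the latent scale (and in the acceptance
simulations, which generate unit-variance exposures directly).

Phenotype missingness is MCAR at a configurable rate (default 0.2%),
consistent with the reported absence of differential missingness. All
randomness flows through one seeded NumPy generator; identical configs give
byte-identical VCF/TSV output.

What passing simulations do **not** show about real data: no LD, no
population stratification (ancestry PCs are accepted as input but never
generated), no pleiotropy (the exclusion restriction holds by construction,
so 2SLS consistency here cannot validate it in any real cohort), no
selection effects or non-MCAR missingness, and single-confounder
confounding. The generator is a test harness for the statistical machinery,
not a population-genetics model.

## Problem sizes and numerical conventions

Monte-Carlo suites use 300 replicates for instrument-strength checks (at
the published analysis Ns of 5180–5396), 500 replicates of n = 5000 for
parameter recovery, and 500 replicates of n = 2000 for test calibration —
sizes at which the binomial/Monte-Carlo error bands are several times
tighter than the assertions they support. Least squares uses
`numpy.linalg.lstsq`; designs with condition number above 1e10 are rejected
as collinear. A perfect first-stage fit reports F = +inf with the flag set.
Partial correlations with residual variance below 1e−10 of the original are
rejected rather than returning rounding noise. Ties in the instrument
search are broken lexicographically by SNP id, making every pipeline output
a deterministic function of (data, config).

## Known limitations

- The orientation/selection over-fitting is reproduced, not corrected; the
  optional split-sample mode (orient and select on one half, estimate on the
  other) is the obvious extension and is not implemented.
- Just-identified 2SLS with a weak instrument has heavy-tailed sampling
  error; replicate means are only meaningful at adequate n·R² (the recovery
  suites run at n·R² ≥ 30).
- No LIML/GMM estimators, no over-identification tests (the design is
  just-identified by construction), no multiple-testing adjustment (none is
  applied in the emulated analysis; α = 0.05 two-sided throughout).
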