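# Methods

## Forward model

The kinetic model is the standard two-compartment linear mammillary system
with first-order elimination from the central (plasma) compartment, driven
by a piecewise-constant infusion. All amounts and volumes are per body
surface area (dose in mg/m², V in L/m²), so absolute BSA never enters. The
protocol infusion delivers 10% of the dose over the first 0.5 h and the
remaining 90% over 23.5 h; "24 h" samples are end-of-infusion.

Within each constant-rate segment the system is affine-linear and is solved
exactly in the eigenbasis of the 2×2 rate matrix (closed-form eigenvalues;
the `(e^{wτ}−1)/w` factor is computed with `expm1` and has the limit τ as
w→0, so near-degenerate, effectively one-compartment parameter sets remain
well defined). The state is propagated across segment boundaries, making the
curve continuous everywhere. A generic adaptive ODE integration is retained
purely as a test oracle; the closed form matches it to better than 1e-6
relative over random parameter and dose draws, satisfies mass balance
against numeric quadrature to 1e-6, and decays strictly after the infusion
ends.

The internal concentration unit is mg/L; micromolar output passes through a
single conversion point using the methotrexate molar mass 454.44 g/mol.
Clearance is CL = k_e·V, reported in mL/min/m².

## MAP estimation from sparse monitoring

Each course contributes ≥ 2 timed plasma levels (protocol times 24 and 42 h,
plus 48 h and 6-hourly samples during delayed excretion; all samples in
(0, 200] h enter the fit). The objective is the negative log posterior over
θ = log(V, k_e, k_cp, k_pc):

- **Priors.** Per-parameter log-normals moment-matched so the original-scale
  mean ± SD equal the quoted population values (V = 9.03 ± 4.70, k_e = 0.7 ±
  0.22, k_cp = 0.08 ± 0.050, k_pc = 0.11 ± 0.0038). The penalty is quadratic
  in θ, so the prior mode in the optimized parameterization is exp(μ). The
  source analysis does not state the prior family; a Gaussian-on-original-
  scale family is provided as an alternative (`PriorSpec(family="normal")`).
  The k_pc prior SD is kept exactly as quoted although it is suspiciously
  tight; it is a plain config value and can be overridden.
- **Residual model.** Proportional Gaussian error, default CV 10% with a
  0.05 µM additive floor, evaluated at the *observed* concentration (fixed
  weights — the classical MAP-TDM convention). This makes the likelihood an
  ordinary weighted sum of squares, so as the assay SD grows the estimate
  shrinks exactly to the prior mode, and estimates are invariant to whether
  concentrations are supplied in µM or mg/L.
- **Optimization.** L-BFGS-B in log space from a fixed five-point multistart
  (prior mode, ± one prior SD on log-V and log-k_e), followed by a
  Nelder-Mead polish; best objective wins, ties break toward the earlier
  start. The procedure is fully deterministic: identical inputs give
  bit-identical results. Non-convergence on every start is flagged, never
  silent.
- **Dose branches.** Courses are routed by the dose actually infused
  (< 4 g/m² vs ≥ 4 g/m²) to per-branch prior sets. Nothing in the source
  distinguishes the two bicompartmental variants structurally, so the
  defaults are identical; the split exists so dose-reduced courses can be
  given their own priors.
- **Below-quantitation samples** carry the quantitation limit and are
  excluded from the likelihood by default (`include_blq=True` imputes them
  at the limit).

Laplace (inverse numeric Hessian) standard errors of the log-parameters are
computed lazily. Sparse 24/42/48 h sampling identifies clearance but not the
distribution constants individually: under the priors' own dispersion with
10% noise, median relative clearance error is ≈ 7% (< 15% guaranteed by the
acceptance suite) with Spearman(true, estimated) ≈ 0.99, while k_cp/k_pc
posteriors stay near the prior.

Per-patient summaries average levels and clearance across courses;
intra-patient variability is the coefficient of variation 100·SD/mean
(sample SD, n−1), defined only with ≥ 2 courses.

## Synthetic cohort generator

The generator emulates the study conditions: n = 200 patients by default,
log-uniform ages on 1–18 y (median ≈ 4.2 y), 55.4% male, four courses of
5 g/m², Hardy-Weinberg genotypes at the six candidate SNPs with default
minor-allele frequencies taken from the published genotype distributions
where derivable (rs4149056 0.167, rs2306283 0.417, rs1045642 0.475,
rs717620 0.179, rs9895420 0.156, rs7317112 0.274).

Population kinetics (V = 9.03 L/m², k_e = 1.12 h⁻¹, k_cp = 0.05 h⁻¹,
k_pc = 0.06 h⁻¹) were calibrated once, by a small grid search against the
published cohort medians, so the noise-free typical course reproduces 24 h ≈
41 µM, 42 h ≈ 0.55 µM, 48 h ≈ 0.39 µM and clearance ≈ 169 mL/min/m² (the
published median clearance is 159.8, IQR 123.8–192.0). Note these population
values deliberately differ from the fitting priors, which are the quoted
initial estimates (CL = 105 mL/min/m²): the MAP stage must work with a
prior that is off-center, as it did in the source analysis.

Variability is multiplicative log-normal at three levels: inter-patient
(CV 15% on V, 28% on k_e, 25% on the distribution constants),
inter-occasion (5/17/10/10%), and assay noise (CV 10%). These were chosen to
land near the published intra-patient CVs (≈ 31% for end-of-infusion levels,
≈ 24% for clearance). Covariates act deterministically on elimination: age
multiplies clearance by exp(−0.023·(age−5)) per year (older patients
eliminate more slowly), and the ABCC4 rs7317112 GG genotype multiplies it by
1.3 (recessive, accelerated elimination).

Sampling follows the protocol: 24/42/48 h always, then 6-hourly up to 96 h
while the last observed level exceeds 0.5 µM. Observed levels below
0.05 µM are flagged below-quantitation.

Outcomes: severe HEM and GI are Bernoulli on a logistic scale with baseline
incidences 37.7% and 7.5% (the wild-type rates in the published toxicity
tables), a dominant rs717620 term with odds ratios 4.6 (HEM) and 5.0 (GI),
and a slope of 1 per log10 of the mean end-of-infusion level. Relapse times
are exponential (Weibull optional) under proportional hazards: baseline
0.021/y, HR 0.27 for dominant rs4149056 (protective), 2.39 for age ≥ 10 y,
2.3 for true mean clearance in the cohort's lowest quartile; censoring is
uniform on 4–7 y, giving ≈ 12–14% relapse. Optional switches, off by
default, reduce subsequent doses by 40% after a simulated per-course severe
toxicity and apply a per-course clearance drift.

What the generator does *not* emulate: leukemia biology, concomitant
mercaptopurine, leucovorin pharmacology, kidney function, linkage
disequilibrium between SNPs (draws are independent), or non-proportional
hazards. Passing round-trip tests therefore show the *statistical machinery*
is correct under the assumed data-generating process, not that the published
cohort-specific estimates are reproduced — those require the unavailable
patient-level data.

## Exposure classification

Threshold flags use the protocol's wording: the 24 h flag is ≥ 150 µM
(levels "should be lower than 150"), the 42/48 h flags are strict > 1 µM and
> 0.5 µM. The delayed-excretion flag follows the latest available
post-infusion level against its own threshold (so the median profile
41.09/0.54/0.39 µM carries no flags: monitoring that found 0.39 µM at 48 h
stops). Intensified leucovorin is the OR over courses of the 48 h flag.

Quartiles use linear-interpolation empirical percentiles with ties at a
cut-point going to the lower quartile; a constant sample degenerates to Q1
with a warning. Quartile assignment is invariant to monotone unit changes.
High exposure = mean 24 h level in Q4 or mean clearance in Q1. Quartiles are
computed over per-patient means (the per-patient average is the analysis
unit throughout).

## Association layer

- **Exact tests.** Two-sided Fisher p by hypergeometric enumeration; the
  effect estimate is the conditional MLE of the odds ratio given both
  margins with its exact conditional CI (matching the convention of R's
  `fisher.test`, which the source analysis used). Every result carries an
  explicit direction label because printed 2×2 ORs depend on row
  orientation. A zero row/column margin raises an error for the OR (the
  published tables print NA in that case); `fisher_pvalue` still returns p.
- **Linear models.** OLS (statsmodels) on the endpoint, log10-transformed
  for end-of-infusion levels (the published per-year coefficients ≈ 0.01 are
  consistent with a log10 scale; the transform is fixed and documented
  here). Univariate screens and a joint model; each term's p is a
  likelihood-ratio test against the model without it (χ²₁), with optional
  age×SNP interaction terms. Rank-deficient designs raise a collinearity
  error at the API level; the pipeline prunes degenerate (monomorphic or
  coincident) codings before joint fits, which small cohorts routinely
  produce. A patient-random-intercept mixed model (REML) is available for
  per-course endpoints; its random-intercept variance is clamped at ≥ 0.
- **Survival.** Cox proportional hazards via lifelines (Efron ties), Wald
  CIs, model LRT; zero events raise an error, and monotone-likelihood
  non-convergence is flagged (a ridge-stabilized refit is returned with
  `converged=False`) rather than silently reported.
- **Rank tests.** Kruskal-Wallis with tie correction; for exactly two small
  groups (each ≤ 10) the exact rank-sum p is used instead of the χ²
  approximation — complete separation of 3 vs 3 then correctly reports
  p = 0.1, not significance. Dunn's pairwise z-tests (pooled ranks, tie
  correction) with Bonferroni/Holm/none adjustment are implemented here
  because no installed package provides them.
- **Multiplicity.** Bonferroni by default with an explicit, configurable
  family size (adjusted p = min(1, p·m)); Holm and Benjamini-Hochberg via
  statsmodels when the family is the p-values at hand. Raw and adjusted
  values are always reported together.
- **Normality screening.** Shapiro-Wilk as a gatekeeper that warns only; it
  never switches tests silently.

## Numerical and design notes

- Genetic codings are deterministic functions of the minor-allele count;
  dominant + recessive = additive is enforced as a test invariant.
- The MAP shrinkage invariant is monotone in the prior-standardized log
  metric (the norm of the standardized deviation from the prior mode);
  individual coordinates can wiggle because the parameters are correlated.
- CSV round-trips are exact: floats are written with `repr` and read with
  pandas' round-trip parser.
- Type-I error calibration (1000 null cohorts of n = 200): OLS-LRT and Cox
  Wald sit at ≈ 5%; Fisher's exact test is inherently conservative at this
  size (≈ 3.5–4%), which is expected behavior of the discrete test, not an
  implementation artifact.
- Problem sizes in the validation suite — 100 oracle draws, 200 recovery
  courses, 1000 calibration replicates of n = 200, one n = 5000 round-trip
  cohort — were chosen as the smallest sizes at which the targeted
  tolerances are comfortably resolvable.

## Known limitations

- No 7-hydroxymethotrexate metabolite kinetics, saturable elimination, or
  intracellular polyglutamate dynamics.
- No population (mixed-effects) PK estimation and no full posterior
  (MCMC); MAP point estimates with Laplace SEs only.
- The LR/SHR dose-branch distinction is structural plumbing only, since the
  source never specifies how the two variants differ.
- Below-quantitation handling is exclusion or simple imputation at the
  limit; no censored-likelihood (M3) integration.
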