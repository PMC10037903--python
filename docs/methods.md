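# Methods

`pfasmeth` implements an analysis chain for studies linking prenatal
chemical exposure panels (PFAS measured in first-trimester maternal
plasma) to newborn cord-blood DNA methylation and birth outcomes. This
note documents the models, their assumptions, the main numerical choices,
and what the synthetic validation does and does not establish.

## Exposure processing

Left-censored analyte concentrations below the analytical limit of
detection (LOD) are substituted by LOD/√2, the standard convention for
log-normal-like environmental analytes. Each analyte is then classified by
its non-detect fraction *f*:

* *f* > 0.80 — excluded from analysis;
* 0.40 ≤ *f* ≤ 0.80 — dichotomized (detected vs not) and modeled
  categorically;
* *f* < 0.40 — modeled as a continuous natural-log-transformed
  concentration.

The boundary fractions 0.40 and 0.80 are assigned to the categorical class
(configurable). Missing categorical covariates (smoking, race indicator)
are completed by a single seeded draw from the empirical distribution of
complete cases — the first step of multiple imputation, run once; the seed
is recorded in run metadata.

## BS/oxBS decomposition (MLML)

Bisulfite (BS) betas measure 5-mC + 5-hmC; oxidative-bisulfite (oxBS)
betas measure 5-mC. Each pair is treated as two binomial observations of a
point on the (5-mC, 5-hmC, unmethylated) simplex with configurable
pseudo-trial weights (default 100 per assay, since array betas carry no
read counts). For this two-assay design the constrained ML solution is
closed-form: `(p_m, p_h) = (oxbs, bs − oxbs)` when `bs ≥ oxbs`, otherwise
the boundary solution `p_h = 0` with `p_m` the weight-pooled mean.
Estimates are therefore never negative and always sum to one with the
unmethylated residual. A dense grid-search maximizer of the joint binomial
likelihood serves as the oracle in the validation suite (agreement within
1e-3 across a 101×101 input lattice). Sites whose mean total methylation
is below 0.1 are removed before per-type analysis, since 5-hmC carries no
signal there.

## Site-wise beta regression

Methylation proportions are modeled with a beta law, logit mean link, and
log-parameterized precision φ (Ferrari–Cribari-Neto parameterization). The
EWAS structure — thousands of regressions sharing one design matrix — is
exploited by a vectorized Fisher-scoring loop with closed-form expected
information, per-site step halving, and per-site convergence tracking. The
engine matches `statsmodels` `BetaModel` coefficients to ~1e-6 on shared
fits and is several hundred times faster at EWAS scale.

Two finite-sample corrections matter at cohort size (n ≈ 141 with 12
design columns):

* reported standard errors carry the classical ML variance adjustment
  n/(n − p − 1), since information-based variances understate
  finite-sample spread by about that factor (likelihood-ratio statistics
  show the same inflation, so this is not a Wald artifact);
* p-values use a Student-t reference with the residual degrees of freedom,
  matching the reporting convention of GAMLSS-style fitters.

Without both, genomic inflation under a correctly specified global null
sits near λ ≈ 1.06–1.13; with them the 20-run mean is ≈ 1.02. λ is
defined as the median 1-df chi-square quantile of the observed p-values
divided by 0.4549.

The three model families mirror the study design: total methylation with
parity, smoking, race, infant sex, four cell-type proportions (CD4T, CD8T,
granulocytes, nRBC) and two batch components; the same model plus a
sex × exposure interaction, with sex-stratified follow-up fits (dropping
the sex covariate) at sites screened at interaction q < 0.05; and the
type-interaction family below, screened at q < 0.2 with per-type follow-up
at q < 0.05. Stratified BH uses the screened-set denominator
(configurable). Non-converged sites are excluded from BH denominators and
counted in the run report.

## Type-interaction beta mixed model

The 5-mC and 5-hmC values of one subject at one site are two observations
of a shared state, stacked into a long matrix (two rows per subject) with
a Type indicator (5-mC reference). The model adds a Gaussian subject
random intercept and a separate precision per methylation type:

    logit μ_ij = x_ij'β + b_i,  y_ij ~ Beta(μ_ij, φ_type(j)),  b_i ~ N(0, σ_b²).

The marginal likelihood integrates b_i by adaptive Gauss–Hermite
quadrature: an inner damped Newton (fixed iteration count, so the
objective is deterministic) locates each subject's posterior mode and
curvature, and 15 nodes (configurable, ≥ 9) are recentered and rescaled
accordingly. Precisions are optimized on the log scale, which guarantees
positivity and leaves the ML point estimates of φ unchanged relative to an
identity-scale parameterization; fixed-effect SEs come from a
central-difference observed information at the optimum. σ_b is bounded
below at 1e-4 on the standard-deviation scale; fits near that bound are
flagged as boundary cases and agree with independent-rows fits to within
0.02.

Validation plants a Type × exposure coefficient of 0.6 at n = 70 and
recovers it within ±0.1 in mean over 300 replicates; the null Wald
rejection rate at α = 0.05 stays inside 0.05 ± 0.02. These checks run on
data generated from the model's own beta mixed process. Through the full
measurement path (beta assay noise plus MLML subtraction) the per-type
signal at low 5-hmC levels is attenuated and boundary zeros must be
clamped (the pipeline clamps MLML output at 1e-3, below assay resolution,
rather than 1e-6, whose logit outliers otherwise dominate per-type fits) —
so pipeline-level recovery of type effects is qualitative (screened-set
membership), not coefficient-exact.

## Regional aggregation

Nearby sites (consecutive same-chromosome probes ≤ 310 bp apart, 1-based
inclusive coordinates) are combined by Stouffer's method on
z = Φ⁻¹(1 − p) with an effective-size correction
√(m + m(m−1)·r̄) using the mean pairwise correlation r̄ of the constituent
sites' methylation values (r̄ = 0 when values are not supplied). A
single-site region keeps its site p-value. Regions are BH-adjusted and
exportable as BED (0-based half-open). This scheme is a documented
re-specification of adjacent-site combination methods and is validated
only against its own closed-form oracle. In the pipeline it triggers for
models with more than 1,000 significant sites.

## Kernel-machine mediation

Mediation of exposure → outcome effects by CpG sets is tested under the
semiparametric model Y = Xγ + Eα_d + h(M) + ε with h in the RKHS of a
kernel over the mediator block (Gaussian with median-heuristic bandwidth
by default; linear optional; proportions enter on the raw scale, logit
optional). H₀: h = 0 is a variance component, tested by the score
statistic Q = r'Kr/(2σ̂²) from the null OLS residuals.

The default p-value treats q = r'Kr / r'r as a ratio of quadratic forms
and evaluates P(ε'(P₀KP₀ − qP₀)ε > 0) exactly by Imhof numerical
inversion — this accounts for the shared randomness of numerator and
residual variance. The two-moment Satterthwaite plug-in (measured type-I
error ≈ 0.017 at n = 141, materially conservative) and the Liu
three-moment method remain as options. The exact method's measured type-I
error is ≈ 0.06 over 1,000 null replicates, and power exceeds 0.8 when
mediators explain ~30% of outcome variance.

Candidate sets must pass a three-tier screen — exposure→methylation
q < 0.05, exposure→outcome p < 0.1, methylation→outcome p < 0.05 (tier-3
regressions adjust for parity, race, smoking, like the outcome models) —
so a small variance-component p is interpretable as a joint-significance
mediation test. Tests run per gene and for the full candidate set; BH is
applied within exposure families. The reported total/direct effect
decomposition (α_t from the model without M; α_d with a linear adjustment
for M, top principal components when sites ≥ subjects) is supplementary
output, not part of the test.

## Synthetic cohort generator

The generator emulates the structure of the motivating study design:

* **Exposures.** Nine analytes, multivariate log-normal on the log scale
  (default pairwise correlation 0.3), left-censored at LOD 0.1 µg/L.
  Default log-scale means/SDs reproduce the published detection profile:
  five well-detected analytes (geometric means 3.2, 5.3, 1.1, 0.37,
  0.12 µg/L; GSDs 1.6–1.9), two moderately detected (~62–65% below LOD),
  two poorly detected (~85% below). Censoring masks the observed value but
  the truth record keeps it, so the LOD/√2 rule's bias is measurable.
* **Covariates.** Parity (Poisson(1), capped at 4), smoking (10%), a
  binary race indicator (7%), infant sex (48.9% male), seven cord-blood
  cell-type proportions (Dirichlet around typical cord-blood means,
  granulocytes dominant), two standard-normal batch components;
  missingness rates for smoking/race default to the study's 9/141 and
  6/141.
* **Methylation.** Total methylation is exactly logit-linear in the
  covariates and any planted exposure effects (trimodal site baselines,
  cell-type coefficients dominating nuisance variation); the 5-hmC share
  of the total follows its own logit. This split keeps p_m + p_h ≤ 1 by
  construction and keeps the total-methylation EWAS correctly specified.
  Sex-interaction effects plant on the total logit via exposure × male;
  type-interaction effects (and 5-hmC-layer mediator effects) shift the
  5-hmC logit directly while 5-mC stays fixed, so the planted value equals
  the type-contrast in exposure slopes. Paired BS/oxBS betas add
  beta-distributed assay noise at a common precision (default 200);
  infinite precision reproduces the truth exactly.
* **Outcomes.** Gestational age (weeks, baseline 39.5) and a size-for-age
  z-score with small parity/smoking/race effects, a planted direct
  exposure effect, planted mediator contributions (centered methylation ×
  coefficient), and Gaussian noise.

Defaults are 141 subjects, 70 with paired oxBS aliquots, and a desk-scale
2,000 sites. All draws descend from one seed through per-stage child
generators (bit-identical reruns).

What the generator does **not** emulate: probe chemistry and IDAT-level
artifacts, between-site correlation (sites are independent given
covariates), genomic clustering of effects, non-beta assay error, or
growth-reference z-score construction. Passing tests therefore establish
the correctness and calibration of the statistical machinery under the
stated generative assumptions, not robustness to real-array artifacts.

## Validation problem sizes

The reproduction script (`scripts/acceptance.py`) and acceptance tests use:
null and recovery EWAS at 2,000 sites × n = 141 over 20 seeded runs;
type-interaction recovery over 300 replicates in the test suite (120 in
the script) and 500 (200) null replicates; kernel-mediation calibration
over 1,000 null and 300 power replicates at n = 141; the MLML oracle over
a 101 × 101 lattice with a 1e-4 grid; BH oracle over 1,000 random
vectors; deconvolution recovery over 50 noisy mixtures of a 350-site,
7-type reference panel.

## Known limitations

* The type-interaction mixed model's quadrature is accurate for the
  two-observation-per-subject design it targets; it is not a general GLMM
  engine.
* The exact mediation p-value costs one n × n eigendecomposition per test;
  for very large candidate sets the Liu method is the faster option.
* Regional aggregation is a p-value combination scheme, not a smoothing
  DMR caller; it inherits the site-level model's calibration.
* The LOD/√2 substitution is a convention, not an estimator; heavily
  censored analytes are dichotomized or excluded rather than modeled with
  censored-likelihood methods.
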