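# Methods

This note documents the statistical machinery, the synthetic-data
generator's assumptions, the defaults and the numerical choices, in the
spirit of a model documentation page: what is computed, under what
assumptions, and what the bundled simulation studies do and do not
establish.

## Cohort survival analysis and the combined exposure score

**Model.** Time-to-event outcomes are analysed with Cox proportional
hazards, h(t|x) = h₀(t)·exp(x'β), maximised by partial likelihood with
Efron's correction for tied event times (the default of modern survival
practice; ties are common in synthetic data with administrative
censoring). Two adjustment sets are used throughout: a minimal model
(age, sex) and a full model adding education, area deprivation (TDI),
ethnicity, family history, BMI, alcohol, physical activity and smoking.
Fitting is delegated to `lifelines.CoxPHFitter`; the test suite checks
agreement with an independently written Newton/BFGS Efron
partial-likelihood solver to 10⁻⁶ on random toy data.

**Exposure score.** The combined score is the weighted pollutant sum
(β₁x₁+β₂x₂+β₃x₃+β₄x₄)·(4/Σβ), with the four weights read off one joint
four-pollutant full-adjustment incidence fit. Models use the per-SD
standardized score (mean 0, SD 1 over the analysis sample). Because the
4/Σβ factor cancels under standardization, the per-SD hazard ratio is
invariant to rescaling all four weights by a positive constant — a
property test asserts this. The score is undefined when Σβ = 0 and this
is rejected explicitly. In scaled-down cohorts the joint fit is noisy
under the strong mutual correlation of the pollutants (defaults 0.68 to
0.94), and the sign of Σβ stabilises only with a few thousand events;
the bundled demo therefore uses n = 25,000 with a ~9% event rate.
Survivor-cohort analyses reuse the incidence-derived weights by default
(`reuse_apes_weights`), since survivor samples are typically too small
to re-derive a stable joint fit; a config switch allows re-derivation.

**Categorical analyses.** Quartiles are sample quantiles of the analysis
cohort with boundary values assigned to the lower category; degenerate
(tied) boundaries raise rather than silently collapsing. The trend test
enters the category as an ordinal 1–4 score. Subgroup heterogeneity is
tested with a single pooled product-term model (stratifier as numeric
code); per-stratum fits drop the stratifier from the adjustment set.
Proportional hazards are checked with the scaled Schoenfeld residual
test on rank-transformed time, fixed so results are comparable across
runs.

## Two-sample Mendelian randomization

Instrument QC mirrors standard cis-instrument practice: association
P < 1×10⁻⁸, position within 1 Mb of the CpG (inclusive at both ends),
greedy LD pruning in ascending-p order discarding any variant with
r² ≥ 0.01 against an already-kept variant (ties broken by variant id so
pruning is deterministic), and removal of weak instruments with
F = (β/SE)² < 10. Harmonization aligns outcome rows to the exposure
effect allele with sign flips for swapped alleles, complement resolution
for strand flips, frequency alignment for palindromic variants outside
the ambiguous EAF window [0.42, 0.58] (dropped inside it), and drops
incompatible allele pairs with logged reason codes.

Estimators: the Wald ratio uses the first-order delta-method SE
(SE_GY/|β_GX|) — the standard primary-analysis convention; IVW is the
fixed-effect weighted mean of per-variant ratios with weights
(β_GX/SE_GY)², identical to zero-intercept weighted least squares of
β_GY on β_GX with weights SE_GY⁻² (asserted to 10⁻¹⁰ on random
instances); no multiplicative over-dispersion scaling is applied to the
headline IVW — heterogeneity is reported separately through Cochran's
Q. MR-Egger orients all β_GX ≥ 0, fits weighted regression with an
intercept, applies the usual multiplicative over-dispersion floor
(σ̂² ≥ 1) and uses t(n−2) p values; with 20 instruments a normal
reference would noticeably inflate the intercept test's size. The
weighted median interpolates the weighted empirical CDF at 0.5
(midpoint rule) and takes its SE from a 1,000-replicate parametric
bootstrap with a fixed recorded seed. Routing: one surviving instrument
→ Wald ratio; two or more → IVW; Egger and weighted median require
three. p values from extreme z-scores are floored at the smallest
positive float so downstream FDR input stays in (0, 1].

FDR is Benjamini–Hochberg (via `statsmodels`) applied to the per-CpG
primary p values within each pollutant family by default — pollutants
are analysed as separate exposure sources — with a pooled-family option.
CpGs without valid instruments stay in the output flagged.

## Colocalization

Per-variant evidence is the Wakefield approximate Bayes factor with
prior effect SD 0.15 on the SD-methylation scale and 0.2 on the
log-odds scale; per-variant priors p₁ = p₂ = 10⁻⁴, p₁₂ = 10⁻⁵
(field-standard single-causal-variant defaults). Hypothesis sums use
the single-causal-per-trait identities and are accumulated in log space
with max-subtraction; H3's "all pairs minus diagonal" term is computed
as a log-difference and set to −∞ when cancellation makes it
non-positive. For regions of ≤ 3 variants the test suite checks the
posteriors against brute-force enumeration of every causal
configuration pair to 10⁻⁹. The colocalization call requires both
PP4 ≥ 0.80 and the lead variant's share of H4 ≥ 0.80; both components
are always reported so either single condition is recoverable.

## Meta-analysis

Study effects are log relative risks; hazard and odds ratios from
cohort studies are pooled as if they were RRs, following common
meta-analytic practice for rare outcomes — logged as an assumption.
Effects and SEs are rescaled to a common increment (default 10 μg/m³)
by log-linearity before pooling. DerSimonian–Laird: fixed weights
SE⁻², Q, τ² = max(0, (Q−df)/(Σw−Σw²/Σw)), random-effects weights
(SE²+τ²)⁻¹, I² = max(0, (Q−df)/Q)·100%, normal-theory CI without
small-sample (Hartung–Knapp) adjustment. Q and I² are scale-invariant;
τ² scales with the square of a common effect/SE rescaling — tests
assert exactly that behaviour. CSV inputs carry RR with a 95% CI,
converted to SE via (log UCL − log LCL)/3.92.

## Gene–environment interaction

The interaction model adds effect-allele dosage (additive 0/1/2
coding), the exposure, and their single product term to the adjusted
Cox model; when principal-component columns are present they join the
adjustment set. The interaction HR is per allele per exposure unit
(per 5 μg/m³ for pollutants, per SD for the combined score — the caller
scales the exposure column). Genotype-stratified fits give the
dose–response picture; classes without events are skipped with logged
warnings. Monomorphic variants are rejected.

## Synthetic-data generator

The generator emulates the structure of a population cohort plus
GWAS-style summary statistics, with every planted parameter recorded in
truth sidecar files.

* **Exposures** are multivariate Gaussian on the raw concentration
  scale, truncated at zero. Defaults (means 10.0/16.2/26.6/43.8 μg/m³,
  SDs 1.06/1.90/7.56/15.60, correlations 0.68–0.94) follow the annual
  means of a UK population cohort.
* **Covariates**: age (truncated normal 56.5 ± 8.1 on 40–70), sex,
  BMI, TDI continuous; education, ethnicity, alcohol, physical
  activity, smoking and family history as integer-coded categories with
  cohort-realistic frequencies. Categories enter linear predictors as
  their integer codes both in generation and in fitting — their role at
  desk scale is adjustment plumbing, not effect estimation. Principal
  components are standard-normal nuisance columns.
* **Genotypes** are binomial(2, EAF) — exact Hardy–Weinberg.
* **Event times** follow a Weibull proportional-hazards model
  (default shape 1.2) sampled by inverse transform, with administrative
  censoring only, so proportional hazards holds exactly and planted
  log-HRs are recoverable without approximation bias. The linear
  predictor is centred at the configured exposure/covariate means, so
  the baseline scale pins the event rate of a reference participant:
  scale 430 gives the ~1.4% 13-year incidence of a population cohort;
  recovery studies use scale 100 (~9%) so each replicate carries enough
  events for a stable fit, and the survivor demo uses scale 40 (~25%
  mortality).
* **Summary statistics** are generated at the summary level, not via
  individual genotypes: marginal effects are the LD-propagation
  Σₖ r_jk √(vₖ/vⱼ) bₖ of the planted per-allele effects (vⱼ = 2fⱼ(1−fⱼ)),
  SEs are 1/√(n·vⱼ) for the unit-variance methylation trait and
  1/√(n·φ(1−φ)·vⱼ) for a case/control outcome with case fraction φ, and
  noise is drawn with covariance diag(SE)·R·diag(SE) so neighbouring
  variants share estimation noise the way real fine-mapping regions do.
  LD is the exponential kernel r(i,j) = exp(−decay·|posᵢ−posⱼ|),
  positive semidefinite by construction. Outcome GWAS effects are
  θ·(methylation effect) plus optional per-variant pleiotropy, which is
  how causal, null and pleiotropic MR scenarios are planted.
* **Meta studies** draw true_logRR + N(0, τ²) + N(0, SEᵢ²) and rescale
  to each study's reporting increment.
* **Seeds**: one integer expands into independent substreams per stage
  via `numpy.random.SeedSequence.spawn`; identical config + seed gives
  byte-identical outputs, which the pipeline manifest verifies with
  SHA-256 hashes.

**What passing tests show — and don't.** The recovery studies establish
that each estimator is consistent and calibrated *under the generator's
assumptions*: exact proportional hazards, Gaussian exposures, linear
covariate effects, single-causal-variant regions, summary-level
normality. Real data violate all of these to some degree (time-varying
exposures, measurement error from exposure modelling, competing risks,
population stratification, multi-causal regions), so green tests
certify the implementation, not the robustness of the scientific
conclusions drawn from any particular dataset.

## Problem sizes and defaults used in the bundled studies

The shipped recovery studies run at desk scale, chosen so that each
study's Monte-Carlo error is several times smaller than its tolerance:
score recovery at n = 5,000 × 200 replicates (~430 events each); MR
recovery with 20 instruments × 200 replicates at consortium-scale SEs;
Egger calibration at 500 replicates of balanced pleiotropy
(SD 0.02); colocalization at 50-variant regions × 100 replicates with
z ≈ 8 signals; τ² recovery at k = 50 × 200 replicates; interaction
recovery at n = 20,000 × 100 replicates and its null calibration at
n = 4,000 × 500 replicates (the test's size does not depend on n).
These sizes are the package's own defaults for its simulation studies;
all are configurable.

## Known limitations

* Single-causal-variant colocalization only; no conditional or
  SuSiE-style multi-signal decomposition.
* No competing-risk or multi-state survival modelling; incidence and
  survivor cohorts are independent tables.
* No trans-mQTL instruments, multivariable MR or Steiger filtering.
* The meta-analysis treats reported HR/OR as RR and offers no
  publication-bias diagnostics.
* Exposure uncertainty (land-use-regression modelling error) is outside
  the generator; exposures are treated as measured.
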