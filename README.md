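# apesmr

Tools for studying how combined ambient air pollution relates to disease
risk and survival, and whether DNA methylation sits on the causal path —
built for epidemiologists and genetic epidemiologists who work with
cohort tables and GWAS/mQTL summary statistics.

The package implements five analysis stages around one synthetic-data
generator with planted ground truth, so every estimator ships with
recovery tests that do not require access-controlled data:

1. **Combined exposure score + cohort survival analysis.** The Air
   Pollutants Exposure Score (APES) summarises four pollutants
   (PM₂.₅, PM₁₀, NO₂, NOₓ; annual means in μg/m³) as

   APES = (β₁x₁ + β₂x₂ + β₃x₃ + β₄x₄) · (4 / Σβ),

   with weights βᵢ taken from one joint four-pollutant multivariable Cox
   model. Cox proportional-hazards models (Efron ties) provide quartile
   contrasts, ordinal trend tests, per-increment and per-SD hazard
   ratios, Kaplan–Meier/log-rank comparisons, Schoenfeld-residual
   diagnostics and subgroup analyses with product-term interaction p
   values.
2. **Two-sample epigenetic Mendelian randomization.** Each CpG site is
   an exposure proxied by its cis-mQTLs (P < 1×10⁻⁸, within 1 Mb,
   greedy LD pruning at r² < 0.01, F = (β/SE)² ≥ 10). Estimators: Wald
   ratio (β_GY/β_GX, SE = SE_GY/|β_GX|), fixed-effect IVW with weights
   (β_GX/SE_GY)², MR-Egger with its pleiotropy-testing intercept, and
   the weighted median with bootstrap SE; Cochran's Q for heterogeneity
   and Benjamini–Hochberg FDR across CpGs within each pollutant family.
3. **Colocalization.** Wakefield approximate Bayes factors
   (log ABF = ½log(1−r) + z²r/2, r = W/(V+W)) feed the standard
   five-hypothesis posterior (PP0–PP4) plus per-variant shared-causal
   posteriors, with a dual decision rule at the 0.80 threshold.
4. **Random-effects meta-analysis.** Study effects are rescaled to a
   common exposure increment by log-linearity and pooled with
   DerSimonian–Laird (Q, τ², I², normal-theory CI).
5. **Gene–environment interaction.** Additive-dosage × exposure product
   terms in adjusted Cox models, with genotype-stratified dose–response
   estimates.

Cox model fitting, Kaplan–Meier estimation, the log-rank test and the
Schoenfeld-residual test are backed by `lifelines`; BH-FDR by
`statsmodels`. The MR estimators, colocalization engine, meta-analysis
and the exposure score are implemented here and verified against
independent oracles in the test suite.

## Worked example

`examples/` holds one short script per capability. For instance,
deriving the exposure score in a simulated cohort of 25,000 with a
planted PM₂.₅ log-hazard of 0.10 per μg/m³:

```bash
$ python examples/01_exposure_score.py
cohort: 25000 participants, 2112 events
derived weights (log-hazard per ug/m3):
   pm25: +0.1032
   pm10: +0.0158
    no2: +0.0186
    nox: -0.0019
per-SD score HR 1.268 (95% CI 1.215-1.323), p=1.59e-27
```

The joint Cox fit recovers the planted PM₂.₅ weight (0.103 vs 0.10);
the per-SD score hazard ratio of 1.27 says one standard deviation more
combined exposure multiplies the event hazard by 1.27 in this
simulation. The other examples run the MR estimators against a planted
causal effect (`02`), separate shared- from distinct-causal-variant
regions (`03`, PP4 = 1.000 vs PP3 = 1.000), pool seven simulated studies
(`04`), fit a planted gene–pollution interaction (`05`), and drive the
whole pipeline end to end with a hash manifest (`06`).

A thin CLI wraps the same functions for shell use:

```bash
apesmr all --config myrun.yaml --seed 1 --outdir out/
```

with subcommands `simulate`, `cohort`, `mr`, `coloc`, `meta`,
`interact` and `all`; the YAML config mirrors
`apesmr.pipeline.RunConfig`.

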