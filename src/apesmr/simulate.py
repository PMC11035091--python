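"""Synthetic data generation with known ground truth.

Every input the pipeline consumes — an individual-level cohort with
time-to-event outcomes, cis-region mQTL and disease-GWAS summary
statistics, and study-level meta-analysis inputs — can be generated
here with planted parameters, so each downstream estimator has a
recoverable truth to be tested against.

Design notes
------------
* Exposures are multivariate Gaussian on the raw concentration scale
  (annual means, μg/m³), truncated at zero.
* Event times follow a Weibull proportional-hazards model sampled by
  inverse transform; censoring is administrative only, so the
  proportional-hazards assumption holds exactly.
* GWAS/mQTL summary statistics are generated directly at the summary
  level: marginal effects are the LD-propagation of the planted
  per-variant effects, and estimation noise is drawn with covariance
  ``diag(SE) @ R @ diag(SE)`` so neighbouring variants share noise the
  way real fine-mapping regions do.
* A single integer seed expands into independent substreams per stage
  via ``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CohortConfig",
    "RegionConfig",
    "MetaStudy",
    "generate_cohort",
    "generate_ld_matrix",
    "generate_mqtl_summary",
    "generate_outcome_gwas",
    "generate_meta_studies",
]

POLLUTANTS = ("pm25", "pm10", "no2", "nox")

#: covariates adjusted for in the minimally and fully adjusted models
MODEL1_COVARIATES = ("age", "sex")
MODEL2_COVARIATES = MODEL1_COVARIATES + (
    "education",
    "tdi",
    "ethnicity",
    "family_history",
    "bmi",
    "alcohol",
    "physical_activity",
    "smoking",
)

# Annual-mean concentration distributions typical of a UK population
# cohort (μg/m³), with the strong mutual correlation of co-emitted
# pollutants.
_DEFAULT_MEANS = {"pm25": 10.0, "pm10": 16.2, "no2": 26.6, "nox": 43.8}
_DEFAULT_SDS = {"pm25": 1.06, "pm10": 1.90, "no2": 7.56, "nox": 15.60}
_DEFAULT_CORR = np.array(
    [
        [1.00, 0.85, 0.87, 0.85],
        [0.85, 1.00, 0.71, 0.68],
        [0.87, 0.71, 1.00, 0.94],
        [0.85, 0.68, 0.94, 1.00],
    ]
)


@dataclass
class CohortConfig:
    """Configuration for an individual-level cohort with survival outcomes.

    ``incidence_loghr`` maps column names (pollutants, covariates, variant
    dosage columns) to log-hazard coefficients per raw unit; pairs in
    ``interaction_loghr`` map ``(variant_id, exposure_column)`` to the
    per-allele, per-raw-unit product-term coefficient.  Exposures and
    continuous covariates enter the linear predictor centred at their
    configured means, so the Weibull baseline (``weibull_shape``,
    ``weibull_scale`` in years) fixes the event rate of a reference
    participant.
    """

    n_participants: int = 20_000
    exposure_means: dict = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    exposure_sds: dict = field(default_factory=lambda: dict(_DEFAULT_SDS))
    exposure_correlation: np.ndarray = field(
        default_factory=lambda: _DEFAULT_CORR.copy()
    )
    age_mean: float = 56.5
    age_sd: float = 8.1
    age_range: tuple = (40.0, 70.0)
    female_proportion: float = 0.54
    bmi_mean: float = 27.4
    bmi_sd: float = 4.8
    tdi_mean: float = -1.3
    tdi_sd: float = 3.1
    smoking_freqs: tuple = (0.55, 0.34, 0.11)  # never / former / current
    physical_activity_freqs: tuple = (0.16, 0.33, 0.51)  # low / moderate / high
    alcohol_freqs: tuple = (0.08, 0.71, 0.21)
    education_freqs: tuple = (0.33, 0.34, 0.33)
    ethnicity_freqs: tuple = (0.94, 0.06)
    family_history_prevalence: float = 0.10
    variant_ids: tuple = ()
    effect_allele_freqs: tuple = ()
    n_principal_components: int = 0
    incidence_loghr: dict = field(default_factory=dict)
    interaction_loghr: dict = field(default_factory=dict)
    weibull_shape: float = 1.2
    # default scale puts the 13-year cumulative incidence near 1.4% at the
    # reference linear predictor, matching a population cohort's CRC rate
    weibull_scale: float = 430.0
    censor_horizon_years: float = 13.0
    seed: int = 0

    def validate(self) -> None:
        r = np.asarray(self.exposure_correlation, dtype=float)
        if r.shape != (4, 4) or not np.allclose(r, r.T):
            raise ValueError("exposure_correlation must be a symmetric 4x4 matrix")
        if not np.allclose(np.diag(r), 1.0):
            raise ValueError("exposure_correlation must have a unit diagonal")
        if np.linalg.eigvalsh(r).min() < -1e-10:
            raise ValueError(
                "exposure_correlation is not positive semidefinite: "
                f"min eigenvalue {np.linalg.eigvalsh(r).min():.3g}"
            )
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        for name in POLLUTANTS:
            if self.exposure_sds[name] <= 0:
                raise ValueError(f"exposure SD for {name} must be > 0")
        for freqs in (
            self.smoking_freqs,
            self.physical_activity_freqs,
            self.alcohol_freqs,
            self.education_freqs,
            self.ethnicity_freqs,
        ):
            arr = np.asarray(freqs, float)
            if (arr < 0).any() or (arr > 1).any() or abs(arr.sum() - 1) > 1e-9:
                raise ValueError(f"category frequencies must lie in [0,1] and sum to 1: {freqs}")
        for f in self.effect_allele_freqs:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"effect-allele frequency {f} outside [0,1]")
        if not 0.0 <= self.family_history_prevalence <= 1.0:
            raise ValueError("family_history_prevalence outside [0,1]")
        if self.censor_horizon_years <= 0:
            raise ValueError("censor_horizon_years must be > 0")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ValueError("Weibull shape and scale must be > 0")
        if len(self.variant_ids) != len(self.effect_allele_freqs):
            raise ValueError("variant_ids and effect_allele_freqs lengths differ")


@dataclass
class RegionConfig:
    """A cis-region around one CpG site with planted genetic effects.

    ``mqtl_effects`` are per-allele effects on methylation in SD units;
    ``causal_effect`` is the log-odds of disease per SD methylation; the
    optional ``pleiotropic_effects`` are direct per-variant log-odds
    contributions bypassing methylation.
    """

    cpg_id: str = "cg00000001"
    cpg_chrom: str = "1"
    cpg_position: int = 1_000_000
    variant_positions: tuple = ()
    effect_allele_freqs: tuple = ()
    mqtl_effects: tuple = ()
    ld_decay: float = 1e-5  # per basepair
    n_mqtl: int = 30_000
    n_cases: int = 16_871
    n_controls: int = 26_328
    causal_effect: float = 0.0
    pleiotropic_effects: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if not self.variant_positions:
            raise ValueError("at least one variant position is required")
        pos = np.asarray(self.variant_positions)
        if not (np.diff(pos) > 0).all():
            raise ValueError("variant positions must be strictly increasing")
        n = len(self.variant_positions)
        if len(self.effect_allele_freqs) != n or len(self.mqtl_effects) != n:
            raise ValueError("per-variant field lengths do not match variant_positions")
        if self.pleiotropic_effects and len(self.pleiotropic_effects) != n:
            raise ValueError("pleiotropic_effects length mismatch")
        if self.n_mqtl < 2:
            raise ValueError("mQTL sample size must be >= 2")
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("case and control counts must each be >= 2")
        if self.ld_decay < 0:
            raise ValueError("LD decay must be non-negative")

    @property
    def n_variants(self) -> int:
        return len(self.variant_positions)

    @property
    def variant_ids(self) -> list:
        return [f"rs{self.cpg_id.lstrip('cg')}_{i}" for i in range(self.n_variants)]


@dataclass
class MetaStudy:
    """One study's reported effect for meta-analysis.

    ``effect`` is a log relative risk at the study's own exposure
    ``increment`` (μg/m³); ``se`` its standard error.
    """

    study_id: str
    effect: float
    se: float
    increment: float = 10.0

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError(f"study {self.study_id}: SE must be > 0")
        if self.increment <= 0:
            raise ValueError(f"study {self.study_id}: increment must be > 0")


def _rngs(seed: int, n: int) -> list:
    return [np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(n)]


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate a cohort table under a Weibull proportional-hazards model.

    Returns a DataFrame with one row per participant: pollutant exposures,
    covariates (categorical ones as integer codes), per-variant effect-allele
    dosages in Hardy–Weinberg proportions, optional principal-component
    columns, and ``time`` (years) / ``event`` columns where ``time`` is the
    minimum of the latent event time and the administrative horizon.
    """
    config.validate()
    (rng_exp, rng_cov, rng_gen, rng_event, rng_pc) = _rngs(config.seed, 5)
    n = config.n_participants

    means = np.array([config.exposure_means[p] for p in POLLUTANTS])
    sds = np.array([config.exposure_sds[p] for p in POLLUTANTS])
    cov = np.asarray(config.exposure_correlation) * np.outer(sds, sds)
    exposures = rng_exp.multivariate_normal(means, cov, size=n, method="cholesky")
    exposures = np.clip(exposures, 0.0, None)

    df = pd.DataFrame(exposures, columns=list(POLLUTANTS))
    df.insert(0, "participant_id", [f"P{i:07d}" for i in range(n)])

    lo, hi = config.age_range
    age = rng_cov.normal(config.age_mean, config.age_sd, size=n)
    df["age"] = np.clip(age, lo, hi)
    df["sex"] = (rng_cov.random(n) < config.female_proportion).astype(int)  # 1 = female
    df["education"] = rng_cov.choice(len(config.education_freqs), n, p=config.education_freqs)
    df["tdi"] = rng_cov.normal(config.tdi_mean, config.tdi_sd, size=n)
    df["ethnicity"] = rng_cov.choice(len(config.ethnicity_freqs), n, p=config.ethnicity_freqs)
    df["family_history"] = (rng_cov.random(n) < config.family_history_prevalence).astype(int)
    df["bmi"] = np.clip(rng_cov.normal(config.bmi_mean, config.bmi_sd, size=n), 15.0, None)
    df["alcohol"] = rng_cov.choice(len(config.alcohol_freqs), n, p=config.alcohol_freqs)
    df["physical_activity"] = rng_cov.choice(
        len(config.physical_activity_freqs), n, p=config.physical_activity_freqs
    )
    df["smoking"] = rng_cov.choice(len(config.smoking_freqs), n, p=config.smoking_freqs)

    for vid, eaf in zip(config.variant_ids, config.effect_allele_freqs):
        df[vid] = rng_gen.binomial(2, eaf, size=n)

    for k in range(config.n_principal_components):
        df[f"pc{k + 1}"] = rng_pc.standard_normal(n)

    # linear predictor, centred so the baseline refers to a participant at
    # the configured exposure/covariate means
    centers = {p: config.exposure_means[p] for p in POLLUTANTS}
    centers.update(
        age=config.age_mean, bmi=config.bmi_mean, tdi=config.tdi_mean
    )
    lp = np.zeros(n)
    for col, beta in config.incidence_loghr.items():
        if col not in df.columns:
            raise KeyError(f"incidence_loghr refers to unknown column {col!r}")
        lp += beta * (df[col].to_numpy(float) - centers.get(col, 0.0))
    for (vid, exp_col), beta in config.interaction_loghr.items():
        x = df[exp_col].to_numpy(float) - centers.get(exp_col, 0.0)
        lp += beta * df[vid].to_numpy(float) * x

    # inverse-transform Weibull PH sampling: S(t) = exp(-(t/λ)^k e^lp)
    u = rng_event.uniform(size=n)
    latent = config.weibull_scale * (-np.log(u) / np.exp(lp)) ** (1.0 / config.weibull_shape)
    horizon = config.censor_horizon_years
    df["time"] = np.minimum(latent, horizon)
    df["event"] = (latent <= horizon).astype(int)
    return df


def generate_ld_matrix(n_variants: int, decay: float, positions) -> np.ndarray:
    """Exponential-decay LD correlation matrix: r(i,j) = exp(-decay·|pos_i-pos_j|).

    Positive semidefinite by construction (exponential kernel on the line).
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if decay < 0:
        raise ValueError("decay must be non-negative")
    pos = np.asarray(positions, dtype=float)
    if pos.shape != (n_variants,):
        raise ValueError("positions length must equal n_variants")
    return np.exp(-decay * np.abs(pos[:, None] - pos[None, :]))


def marginal_effects(true_effects, ld: np.ndarray, eaf) -> np.ndarray:
    """LD-propagated marginal per-allele effects.

    With genotype variances v_j = 2 f_j (1 - f_j), the marginal regression
    coefficient at variant j is Σ_k r_jk sqrt(v_k / v_j) b_k.  Exposed as a
    function so tests can use it as a closed-form oracle.
    """
    b = np.asarray(true_effects, float)
    f = np.asarray(eaf, float)
    v = 2.0 * f * (1.0 - f)
    return (ld * np.sqrt(v[None, :] / v[:, None])) @ b


def _summary_frame(region: RegionConfig, betas, ses, n) -> pd.DataFrame:
    z = betas / ses
    return pd.DataFrame(
        {
            "SNP": region.variant_ids,
            "CHR": region.cpg_chrom,
            "POS": list(region.variant_positions),
            "EA": "A",
            "OA": "G",
            "EAF": list(region.effect_allele_freqs),
            "BETA": betas,
            "SE": ses,
            "P": 2.0 * stats.norm.sf(np.abs(z)),
            "N": n,
        }
    )


def _correlated_noise(rng, ld: np.ndarray, ses: np.ndarray) -> np.ndarray:
    # noise covariance ≈ diag(SE) R diag(SE); eigh handles the PSD boundary
    w, v = np.linalg.eigh(ld)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    return ses * (root @ rng.standard_normal(ld.shape[0]))


def generate_mqtl_summary(region: RegionConfig, ld: np.ndarray) -> pd.DataFrame:
    """Marginal cis-mQTL summary statistics for one CpG's region.

    Effect sizes are in SD-methylation units per effect allele; standard
    errors follow SE_j = 1/sqrt(n · 2 f_j (1-f_j)) for a unit-variance
    methylation trait.
    """
    if ld.shape != (region.n_variants, region.n_variants):
        raise ValueError("LD matrix dimensions do not match the region")
    f = np.asarray(region.effect_allele_freqs, float)
    if ((f <= 0.0) | (f >= 1.0)).any():
        raise ValueError("allele frequencies must lie strictly in (0,1): SE undefined at 0/1")
    rng = _rngs(region.seed, 2)[0]
    v = 2.0 * f * (1.0 - f)
    ses = 1.0 / np.sqrt(region.n_mqtl * v)
    betas = marginal_effects(region.mqtl_effects, ld, f) + _correlated_noise(rng, ld, ses)
    return _summary_frame(region, betas, ses, region.n_mqtl)


def generate_outcome_gwas(region: RegionConfig, ld: np.ndarray) -> pd.DataFrame:
    """Case/control GWAS summary statistics for the disease outcome.

    Each variant's direct log-odds effect is θ·(its methylation effect)
    plus any pleiotropic term; marginals are LD-propagated and noise is
    added at the case/control-implied SE.
    """
    if ld.shape != (region.n_variants, region.n_variants):
        raise ValueError("LD matrix dimensions do not match the region")
    f = np.asarray(region.effect_allele_freqs, float)
    if ((f <= 0.0) | (f >= 1.0)).any():
        raise ValueError("allele frequencies must lie strictly in (0,1): SE undefined at 0/1")
    rng = _rngs(region.seed, 2)[1]
    pleio = np.asarray(region.pleiotropic_effects or np.zeros(region.n_variants), float)
    direct = region.causal_effect * np.asarray(region.mqtl_effects, float) + pleio
    n_total = region.n_cases + region.n_controls
    phi = region.n_cases / n_total
    v = 2.0 * f * (1.0 - f)
    ses = 1.0 / np.sqrt(n_total * phi * (1.0 - phi) * v)
    betas = marginal_effects(direct, ld, f) + _correlated_noise(rng, ld, ses)
    return _summary_frame(region, betas, ses, n_total)


def generate_meta_studies(
    k: int,
    true_log_rr: float,
    tau2: float,
    ses,
    increments=None,
    seed: int = 0,
) -> list:
    """Draw study-level effects under a random-effects model.

    ``true_log_rr`` is per 10 μg/m³; each study's reported effect and SE are
    rescaled to its own ``increment`` by log-linearity.
    """
    if k < 2:
        raise ValueError("a meta-analysis needs at least 2 studies")
    ses = np.asarray(ses, float)
    if ses.shape != (k,) or (ses <= 0).any():
        raise ValueError("ses must be k positive values")
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    increments = np.full(k, 10.0) if increments is None else np.asarray(increments, float)
    if (increments <= 0).any():
        raise ValueError("increments must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    theta = true_log_rr + rng.normal(0.0, np.sqrt(tau2), k) + rng.normal(0.0, ses)
    scale = increments / 10.0
    return [
        MetaStudy(f"study_{i + 1}", theta[i] * scale[i], ses[i] * scale[i], increments[i])
        for i in range(k)
    ]
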