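"""Cohort survival analyses: pollutant exposure score and Cox models.

The combined-exposure score is a weighted sum of the four pollutant
concentrations, with weights taken from their coefficients in one joint
multivariable Cox model and normalised by 4 divided by the coefficient
sum:

    score = (β₁x₁ + β₂x₂ + β₃x₃ + β₄x₄) · (4 / Σβ)

Models enter the score per standard deviation of the analysis sample.
Cox fitting uses Efron handling of ties throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test

from .simulate import MODEL2_COVARIATES, POLLUTANTS

__all__ = [
    "APESWeights",
    "CoxFit",
    "fit_cox",
    "derive_apes_weights",
    "compute_apes",
    "quartile_categories",
    "trend_test",
    "km_logrank",
    "check_proportional_hazards",
    "subgroup_analysis",
]

log = logging.getLogger(__name__)


@dataclass
class APESWeights:
    """Per-pollutant log-hazard weights (per μg/m³) for the combined score."""

    beta_pm25: float
    beta_pm10: float
    beta_no2: float
    beta_nox: float

    def as_array(self) -> np.ndarray:
        return np.array([self.beta_pm25, self.beta_pm10, self.beta_no2, self.beta_nox])

    def validate(self) -> None:
        arr = self.as_array()
        if not np.isfinite(arr).all():
            raise ValueError("all score weights must be finite")
        if arr.sum() == 0:
            raise ValueError(
                "sum of the pollutant coefficients is zero: the 4/Σβ "
                "normalisation — and hence the score — is undefined"
            )


@dataclass
class CoxFit:
    """A fitted proportional-hazards model's per-term contracts."""

    summary: pd.DataFrame  # index: term; columns: coef, se, z, p, ci_lower, ci_upper
    n: int
    n_events: int
    label: str = ""
    _model: object = None

    def coef(self, term: str) -> float:
        return float(self.summary.loc[term, "coef"])

    def se(self, term: str) -> float:
        return float(self.summary.loc[term, "se"])

    def p(self, term: str) -> float:
        return float(self.summary.loc[term, "p"])

    def hr(self, term: str) -> float:
        return float(np.exp(self.summary.loc[term, "coef"]))

    def ci(self, term: str) -> tuple:
        row = self.summary.loc[term]
        return float(row["ci_lower"]), float(row["ci_upper"])


def fit_cox(
    table: pd.DataFrame,
    terms,
    duration_col: str = "time",
    event_col: str = "event",
    label: str = "",
) -> CoxFit:
    """Fit a Cox proportional-hazards model by partial likelihood (Efron ties).

    ``terms`` are the covariate columns entering the linear predictor.
    Raises if there are fewer than two events or a term column is constant
    (which would be inestimable / cause separation-like failures).
    """
    terms = list(terms)
    n_events = int(table[event_col].sum())
    if n_events < 2:
        raise ValueError(f"need at least 2 events to fit a Cox model, got {n_events}")
    for t in terms:
        if table[t].nunique() < 2:
            raise ValueError(f"term {t!r} is constant in the analysis sample")
    sub = table[terms + [duration_col, event_col]].dropna()
    dropped = len(table) - len(sub)
    if dropped:
        log.warning("complete-case analysis dropped %d rows with missing values", dropped)
    cph = CoxPHFitter()
    try:
        cph.fit(sub, duration_col=duration_col, event_col=event_col)
    except Exception as exc:  # convergence / separation diagnostics surfaced
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    s = cph.summary
    out = pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "z": s["z"],
            "p": s["p"],
            "ci_lower": s["coef lower 95%"],
            "ci_upper": s["coef upper 95%"],
        }
    )
    out.index.name = "term"
    return CoxFit(out, n=len(sub), n_events=n_events, label=label, _model=cph)


def derive_apes_weights(
    table: pd.DataFrame,
    covariates=MODEL2_COVARIATES,
    duration_col: str = "time",
    event_col: str = "event",
) -> APESWeights:
    """Pollutant weights from one joint four-pollutant adjusted Cox fit.

    All four pollutants enter a single fully adjusted incidence model; their
    coefficients (log-hazard per μg/m³) become the score weights.
    """
    fit = fit_cox(
        table,
        list(POLLUTANTS) + list(covariates),
        duration_col=duration_col,
        event_col=event_col,
        label="joint four-pollutant model",
    )
    w = APESWeights(*(fit.coef(p) for p in POLLUTANTS))
    w.validate()
    return w


def compute_apes(exposures: pd.DataFrame, weights: APESWeights) -> pd.DataFrame:
    """Raw and per-SD standardized combined exposure score.

    Raw score = Σ βᵢxᵢ · (4/Σβ).  The standardized column has mean 0 and
    SD 1 over the rows supplied (the analysis sample).
    """
    weights.validate()
    b = weights.as_array()
    x = exposures[list(POLLUTANTS)].to_numpy(float)
    raw = (x @ b) * (4.0 / b.sum())
    sd = raw.std(ddof=0)
    if sd == 0:
        raise ValueError("score is constant; cannot standardize")
    return pd.DataFrame(
        {"apes": raw, "apes_std": (raw - raw.mean()) / sd}, index=exposures.index
    )


def quartile_categories(values) -> tuple:
    """Quartile category (1..4, lowest = reference) per value, plus cutpoints.

    Boundary values go to the lower category.  Degenerate (tied) quartile
    boundaries are an error because the categories would collapse.
    """
    v = np.asarray(values, float)
    if len(np.unique(v)) < 4:
        raise ValueError("need at least 4 distinct values to form quartiles")
    cuts = np.quantile(v, [0.25, 0.5, 0.75])
    if len(np.unique(cuts)) < 3:
        dup = cuts[np.where(np.diff(cuts) == 0)[0][0]]
        raise ValueError(f"quartile boundaries collapse at {dup}: too many ties")
    # side="left" sends a value equal to a cutpoint into the lower category
    cats = 1 + np.searchsorted(cuts, v, side="left")
    return cats.astype(int), cuts


def trend_test(
    table: pd.DataFrame,
    categories,
    covariates=MODEL2_COVARIATES,
    duration_col: str = "time",
    event_col: str = "event",
) -> float:
    """Wald p for an ordinal (1–4 coded) exposure term in the Cox model."""
    df = table.copy()
    df["_trend"] = np.asarray(categories, float)
    fit = fit_cox(df, ["_trend"] + list(covariates), duration_col, event_col)
    return fit.p("_trend")


def km_logrank(
    table: pd.DataFrame,
    groups,
    duration_col: str = "time",
    event_col: str = "event",
) -> dict:
    """Kaplan–Meier curves per group plus the (g-1)-df log-rank test."""
    groups = pd.Series(np.asarray(groups), index=table.index)
    labels = groups.unique()
    if len(labels) < 2:
        raise ValueError("need at least 2 groups for a log-rank test")
    curves = {}
    for g in labels:
        mask = groups == g
        if table.loc[mask, event_col].sum() < 1:
            raise ValueError(f"group {g!r} has no events")
        km = KaplanMeierFitter()
        km.fit(table.loc[mask, duration_col], table.loc[mask, event_col], label=str(g))
        curves[g] = km.survival_function_
    res = multivariate_logrank_test(
        table[duration_col], groups, table[event_col]
    )
    return {
        "curves": curves,
        "statistic": float(res.test_statistic),
        "df": len(labels) - 1,
        "p": float(res.p_value),
    }


def check_proportional_hazards(fit: CoxFit, table: pd.DataFrame) -> pd.DataFrame:
    """Scaled-Schoenfeld-residual test of proportional hazards (rank time).

    Returns a per-term frame with the test statistic and p value.
    """
    if fit._model is None:
        raise ValueError("fit does not carry its underlying model")
    if fit.n_events < 1:
        raise ValueError("no events: proportional-hazards test undefined")
    model = fit._model
    cols = list(model.params_.index) + [model.duration_col, model.event_col]
    res = proportional_hazard_test(model, table[cols], time_transform="rank")
    out = res.summary[["test_statistic", "p"]].copy()
    out.index = [ix[0] if isinstance(ix, tuple) else ix for ix in out.index]
    return out


def subgroup_analysis(
    table: pd.DataFrame,
    stratifier: str,
    exposure: str,
    covariates=MODEL2_COVARIATES,
    duration_col: str = "time",
    event_col: str = "event",
) -> dict:
    """Per-stratum exposure effects plus a pooled product-term heterogeneity p.

    Strata that cannot be fitted (no/too few events) are skipped with a
    logged warning rather than failing the whole analysis.  The interaction
    p comes from a single pooled model with an exposure×stratifier product
    term (stratifier entered as a numeric code).
    """
    covariates = [c for c in covariates if c != stratifier]
    strata = {}
    for level, sub in table.groupby(stratifier):
        if sub[event_col].sum() < 2:
            log.warning("stratum %s=%r skipped: <2 events", stratifier, level)
            continue
        try:
            strata[level] = fit_cox(
                sub, [exposure] + covariates, duration_col, event_col,
                label=f"{stratifier}={level}",
            )
        except (ValueError, RuntimeError) as exc:
            log.warning("stratum %s=%r skipped: %s", stratifier, level, exc)
    pooled = table.copy()
    pooled["_product"] = pooled[exposure] * pooled[stratifier].astype(float)
    fit = fit_cox(
        pooled,
        [exposure, stratifier, "_product"] + covariates,
        duration_col,
        event_col,
        label="pooled interaction model",
    )
    return {"strata": strata, "p_interaction": fit.p("_product"), "pooled_fit": fit}
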