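"""Gene–environment interaction in proportional-hazards models.

Tests whether a variant's effect-allele dosage (additive 0/1/2 coding)
modifies the association of an exposure (a pollutant per 5 μg/m³, or the
combined score per SD) with the outcome, via a single product term in an
adjusted Cox model, plus genotype-stratified dose–response estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CoxFit, fit_cox
from .simulate import MODEL2_COVARIATES

__all__ = ["InteractionResult", "fit_interaction", "stratify_by_genotype"]

log = logging.getLogger(__name__)


@dataclass
class InteractionResult:
    variant: str
    exposure: str
    fit: CoxFit
    interaction_coef: float
    interaction_se: float
    interaction_p: float
    main_effect_coef: float
    main_effect_se: float
    model_label: str = ""
    stratified: dict = field(default_factory=dict)  # dosage -> CoxFit

    @property
    def interaction_hr(self) -> float:
        return float(np.exp(self.interaction_coef))

    @property
    def interaction_ci(self) -> tuple:
        lo = self.interaction_coef - 1.959963984540054 * self.interaction_se
        hi = self.interaction_coef + 1.959963984540054 * self.interaction_se
        return float(np.exp(lo)), float(np.exp(hi))


def fit_interaction(
    table: pd.DataFrame,
    variant: str,
    exposure: str,
    covariates=MODEL2_COVARIATES,
    n_pcs: int = 0,
    duration_col: str = "time",
    event_col: str = "event",
    model_label: str = "",
) -> InteractionResult:
    """Product-term interaction model: exposure + dosage + exposure×dosage.

    ``n_pcs`` principal-component columns (pc1..pcN) are appended to the
    adjustment set when present.  The variant must be polymorphic.
    """
    if table[variant].nunique() < 2:
        raise ValueError(f"variant {variant!r} is monomorphic in the analysis sample")
    df = table.copy()
    prod = f"{variant}_x_{exposure}"
    df[prod] = df[variant].astype(float) * df[exposure].astype(float)
    adj = list(covariates) + [f"pc{i + 1}" for i in range(n_pcs)]
    fit = fit_cox(
        df, [exposure, variant, prod] + adj, duration_col, event_col, label=model_label
    )
    return InteractionResult(
        variant=variant,
        exposure=exposure,
        fit=fit,
        interaction_coef=fit.coef(prod),
        interaction_se=fit.se(prod),
        interaction_p=fit.p(prod),
        main_effect_coef=fit.coef(exposure),
        main_effect_se=fit.se(exposure),
        model_label=model_label,
    )


def stratify_by_genotype(
    table: pd.DataFrame,
    variant: str,
    exposure: str,
    covariates=MODEL2_COVARIATES,
    n_pcs: int = 0,
    duration_col: str = "time",
    event_col: str = "event",
) -> dict:
    """Per-genotype-class adjusted exposure effects (dose–response by genotype).

    Returns {dosage: CoxFit}; classes with no events are skipped with a
    logged warning.
    """
    adj = list(covariates) + [f"pc{i + 1}" for i in range(n_pcs)]
    out = {}
    for dosage, sub in table.groupby(variant):
        if sub[event_col].sum() < 2:
            log.warning("genotype class %s=%s skipped: <2 events", variant, dosage)
            continue
        try:
            out[int(dosage)] = fit_cox(
                sub, [exposure] + adj, duration_col, event_col,
                label=f"{variant}={int(dosage)}",
            )
        except (ValueError, RuntimeError) as exc:
            log.warning("genotype class %s=%s skipped: %s", variant, dosage, exc)
    return out
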