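"""Random-effects meta-analysis of study-level exposure effects.

Study effects (log relative risks) are first rescaled to a common exposure
increment (default 10 μg/m³) by log-linearity, then pooled with the
DerSimonian–Laird method-of-moments estimator:

    w_i   = SE_i⁻²                 (fixed-effect weights)
    Q     = Σ w_i (θ_i − θ_FE)²
    τ²    = max(0, (Q − (k−1)) / (Σw − Σw²/Σw))
    w*_i  = (SE_i² + τ²)⁻¹         (random-effects weights)
    I²    = max(0, (Q − (k−1))/Q) · 100%

Confidence intervals are normal-theory (no small-sample adjustment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import MetaStudy

__all__ = ["MetaResult", "rescale_effect", "dersimonian_laird", "forest_table", "read_study_csv"]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class MetaResult:
    pooled_log_rr: float
    se: float
    tau2: float
    q: float
    df: int
    i2: float  # percent
    p: float
    weights: pd.Series  # normalised random-effects weights per study
    increment: float = 10.0

    @property
    def pooled_rr(self) -> float:
        return math.exp(self.pooled_log_rr)

    @property
    def ci(self) -> tuple:
        return (
            self.pooled_log_rr - _Z95 * self.se,
            self.pooled_log_rr + _Z95 * self.se,
        )

    @property
    def rr_ci(self) -> tuple:
        lo, hi = self.ci
        return (math.exp(lo), math.exp(hi))


def rescale_effect(study: MetaStudy, target_increment: float = 10.0) -> MetaStudy:
    """Rescale a study's log RR and SE to a target exposure increment."""
    if target_increment <= 0:
        raise ValueError("target increment must be > 0")
    factor = target_increment / study.increment
    return replace(
        study,
        effect=study.effect * factor,
        se=study.se * factor,
        increment=target_increment,
    )


def dersimonian_laird(studies, target_increment: float = 10.0) -> MetaResult:
    """DerSimonian–Laird random-effects pooling on the log-RR scale."""
    studies = [rescale_effect(s, target_increment) for s in studies]
    k = len(studies)
    if k < 2:
        raise ValueError("meta-analysis needs at least 2 studies")
    theta = np.array([s.effect for s in studies])
    se = np.array([s.se for s in studies])
    w = 1.0 / se**2
    theta_fe = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - theta_fe) ** 2))
    df = k - 1
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - df) / denom)
    w_re = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_re * theta) / np.sum(w_re))
    pooled_se = float(1.0 / math.sqrt(np.sum(w_re)))
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    return MetaResult(
        pooled_log_rr=pooled,
        se=pooled_se,
        tau2=tau2,
        q=q,
        df=df,
        i2=i2,
        p=float(2 * stats.norm.sf(abs(pooled) / pooled_se)),
        weights=pd.Series(w_re / w_re.sum(), index=[s.study_id for s in studies]),
        increment=target_increment,
    )


def forest_table(result: MetaResult, studies) -> pd.DataFrame:
    """Machine-readable forest-plot rows: per-study RR/CI/weight plus the pooled row."""
    rows = []
    for s in studies:
        s10 = rescale_effect(s, result.increment)
        rows.append(
            {
                "study": s.study_id,
                "rr": math.exp(s10.effect),
                "lcl": math.exp(s10.effect - _Z95 * s10.se),
                "ucl": math.exp(s10.effect + _Z95 * s10.se),
                "weight_pct": 100.0 * float(result.weights[s.study_id]),
            }
        )
    lo, hi = result.rr_ci
    rows.append(
        {
            "study": "RE pooled",
            "rr": result.pooled_rr,
            "lcl": lo,
            "ucl": hi,
            "weight_pct": 100.0,
        }
    )
    return pd.DataFrame(rows)


def read_study_csv(path) -> list:
    """Read study-level inputs (id, rr, lcl, ucl, increment) from CSV.

    The 95% CI is converted to a log-scale SE via (log ucl − log lcl)/3.92.
    """
    df = pd.read_csv(path, comment="#")
    required = {"id", "rr", "lcl", "ucl", "increment"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"study CSV missing columns: {sorted(missing)}")
    studies = []
    for _, r in df.iterrows():
        se = (math.log(r["ucl"]) - math.log(r["lcl"])) / 3.92
        studies.append(MetaStudy(str(r["id"]), math.log(r["rr"]), se, float(r["increment"])))
    return studies
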