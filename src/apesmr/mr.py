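"""Two-sample Mendelian randomization of CpG methylation on disease risk.

Each CpG site is one exposure, proxied by its cis-mQTLs.  Instrument QC:
genome-wide-significant cis variants (P < 1e-8, within 1 Mb of the CpG,
boundary inclusive), greedy LD pruning at r² < 0.01 in ascending-p order,
and an F ≥ 10 weak-instrument filter with F = (β/SE)².  Estimators:

* Wald ratio (single instrument): β_GY/β_GX, SE = SE_GY/|β_GX|.
* IVW: inverse-variance-weighted mean of per-variant ratios with weights
  (β_GX/SE_GY)², identical to the zero-intercept weighted regression of
  β_GY on β_GX with weights SE_GY⁻².
* MR-Egger: the same regression with an intercept (after orienting all
  β_GX ≥ 0); the intercept tests directional pleiotropy.
* Weighted median of the ratio estimates, SE by parametric bootstrap.

Per-CpG primary p values receive Benjamini–Hochberg FDR control within
each pollutant family.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CpGSite",
    "InstrumentSet",
    "MREstimate",
    "SelectionThresholds",
    "select_instruments",
    "compute_f_statistic",
    "harmonize",
    "wald_ratio",
    "ivw",
    "cochran_q",
    "egger",
    "weighted_median",
    "bh_fdr",
    "run_epigenetic_mr",
]

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_Z95 = stats.norm.ppf(0.975)


@dataclass
class CpGSite:
    cpg_id: str
    chrom: str
    position: int
    gene: str = ""
    pollutant: str = ""

    def __post_init__(self):
        if self.position < 1:
            raise ValueError("CpG position must be >= 1 (1-based)")


@dataclass
class SelectionThresholds:
    """Instrument QC thresholds (defaults: P<1e-8, ±1 Mb, r²<0.01, F≥10)."""

    p_max: float = 1e-8
    cis_window: int = 1_000_000
    r2_max: float = 0.01
    f_min: float = 10.0


@dataclass
class InstrumentSet:
    """Harmonized exposure/outcome rows proxying one CpG site."""

    cpg_id: str
    table: pd.DataFrame  # columns: SNP, beta_gx, se_gx, beta_gy, se_gy, ea, f_stat
    flag: str = ""

    @property
    def n_snps(self) -> int:
        return len(self.table)


@dataclass
class MREstimate:
    cpg_id: str
    method: str
    beta: float = math.nan  # log-OR of disease per SD methylation
    se: float = math.nan
    p: float = math.nan
    n_snps: int = 0
    q: float = math.nan
    q_df: int = 0
    q_p: float = math.nan
    egger_intercept: float = math.nan
    egger_intercept_se: float = math.nan
    egger_intercept_p: float = math.nan
    fdr_q: float = math.nan
    flag: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def ci(self) -> tuple:
        return (self.beta - _Z95 * self.se, self.beta + _Z95 * self.se)

    @property
    def or_ci(self) -> tuple:
        lo, hi = self.ci
        return (math.exp(lo), math.exp(hi))


def compute_f_statistic(beta: float, se: float) -> float:
    """Instrument-strength F statistic, F = (β/SE)²."""
    if se <= 0:
        raise ValueError("SE must be > 0")
    return (beta / se) ** 2


def select_instruments(
    mqtl: pd.DataFrame,
    cpg: CpGSite,
    ld: np.ndarray | None = None,
    thresholds: SelectionThresholds | None = None,
) -> pd.DataFrame:
    """Cis, significant, LD-pruned, strong instruments for one CpG.

    ``mqtl`` is a summary-statistics frame (SNP/CHR/POS/EA/OA/EAF/BETA/SE/P/N)
    whose row order matches the rows/columns of ``ld`` (pairwise r, not r²).
    Pruning is greedy in ascending-p order: a variant is discarded if its r²
    with any already-kept variant is at or above the threshold.  Returns the
    surviving rows (possibly empty — the caller flags, never raises).
    """
    th = thresholds or SelectionThresholds()
    df = mqtl.reset_index(drop=True).copy()
    df["_row"] = np.arange(len(df))
    cis = (df["CHR"].astype(str) == str(cpg.chrom)) & (
        (df["POS"] - cpg.position).abs() <= th.cis_window
    )
    df = df[cis & (df["P"] < th.p_max)]
    if df.empty:
        return df.drop(columns="_row")
    df = df.sort_values(["P", "SNP"], kind="mergesort")
    kept_rows: list[int] = []
    for _, row in df.iterrows():
        i = int(row["_row"])
        if ld is None or all(ld[i, j] ** 2 < th.r2_max for j in kept_rows):
            kept_rows.append(i)
    out = df[df["_row"].isin(kept_rows)]
    out = out[(out["BETA"] / out["SE"]) ** 2 >= th.f_min]
    return out.sort_values("POS").drop(columns="_row").reset_index(drop=True)


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame, cpg_id: str = "") -> InstrumentSet:
    """Align outcome effect alleles to the exposure rows.

    Rules, applied per shared variant: direct allele match → keep; swapped
    alleles → flip the outcome beta's sign (and EAF); strand flip resolved via
    complements; palindromic variants (A/T or C/G) are dropped when EAF is in
    [0.42, 0.58] and otherwise aligned by allele frequency; incompatible
    allele pairs are dropped.  Every drop is logged with a reason code.
    """
    exp = exposure.set_index("SNP")
    out = outcome.set_index("SNP")
    rows = []
    for snp in exp.index:
        if snp not in out.index:
            log.info("harmonize: %s dropped [missing_in_outcome]", snp)
            continue
        e, o = exp.loc[snp], out.loc[snp]
        ea_e, oa_e = str(e["EA"]).upper(), str(e["OA"]).upper()
        ea_o, oa_o = str(o["EA"]).upper(), str(o["OA"]).upper()
        beta_gy, eaf_o = float(o["BETA"]), float(o["EAF"])
        palindromic = oa_e == _COMPLEMENT.get(ea_e)
        if palindromic:
            if 0.42 <= float(e["EAF"]) <= 0.58 or 0.42 <= eaf_o <= 0.58:
                log.info("harmonize: %s dropped [palindromic_ambiguous]", snp)
                continue
            # align by frequency: both minor or both major means same allele
            if (float(e["EAF"]) < 0.5) != (eaf_o < 0.5):
                beta_gy = -beta_gy
        elif (ea_o, oa_o) == (ea_e, oa_e):
            pass
        elif (ea_o, oa_o) == (oa_e, ea_e):
            beta_gy = -beta_gy
        else:
            flip = (_COMPLEMENT.get(ea_o, "?"), _COMPLEMENT.get(oa_o, "?"))
            if flip == (ea_e, oa_e):
                pass
            elif flip == (oa_e, ea_e):
                beta_gy = -beta_gy
            else:
                log.info("harmonize: %s dropped [allele_mismatch]", snp)
                continue
        rows.append(
            {
                "SNP": snp,
                "beta_gx": float(e["BETA"]),
                "se_gx": float(e["SE"]),
                "beta_gy": beta_gy,
                "se_gy": float(o["SE"]),
                "ea": ea_e,
                "f_stat": compute_f_statistic(float(e["BETA"]), float(e["SE"])),
            }
        )
    table = pd.DataFrame(rows, columns=["SNP", "beta_gx", "se_gx", "beta_gy", "se_gy", "ea", "f_stat"])
    flag = "" if len(table) else "no valid instruments"
    return InstrumentSet(cpg_id=cpg_id, table=table, flag=flag)


def _normal_p(beta: float, se: float) -> float:
    # floored at the smallest subnormal so extreme z-scores stay in (0, 1]
    return max(float(2.0 * stats.norm.sf(abs(beta) / se)), 5e-324)


def wald_ratio(row, cpg_id: str = "") -> MREstimate:
    """Single-instrument ratio estimate with first-order delta-method SE."""
    beta_gx, beta_gy, se_gy = float(row["beta_gx"]), float(row["beta_gy"]), float(row["se_gy"])
    if beta_gx == 0:
        raise ValueError("Wald ratio undefined: exposure beta is zero")
    beta = beta_gy / beta_gx
    se = se_gy / abs(beta_gx)
    return MREstimate(cpg_id, "wald_ratio", beta, se, _normal_p(beta, se), n_snps=1)


def _ratio_weights(t: pd.DataFrame) -> tuple:
    ratios = t["beta_gy"].to_numpy(float) / t["beta_gx"].to_numpy(float)
    weights = (t["beta_gx"].to_numpy(float) / t["se_gy"].to_numpy(float)) ** 2
    return ratios, weights


def ivw(instruments: InstrumentSet) -> MREstimate:
    """Fixed-effect inverse-variance-weighted estimate over ratio estimates."""
    t = instruments.table
    if len(t) < 2:
        raise ValueError("IVW needs >= 2 instruments; use wald_ratio")
    ratios, w = _ratio_weights(t)
    beta = float(np.sum(w * ratios) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    est = MREstimate(
        instruments.cpg_id, "ivw", beta, se, _normal_p(beta, se), n_snps=len(t)
    )
    est.q, est.q_df, est.q_p = cochran_q(instruments, beta)
    return est


def cochran_q(instruments: InstrumentSet, ivw_beta: float) -> tuple:
    """Heterogeneity of the per-instrument ratios: Q, df, chi-square p."""
    ratios, w = _ratio_weights(instruments.table)
    q = float(np.sum(w * (ratios - ivw_beta) ** 2))
    df = len(ratios) - 1
    return q, df, float(stats.chi2.sf(q, df)) if df > 0 else 1.0


def egger(instruments: InstrumentSet) -> MREstimate:
    """MR-Egger weighted regression with intercept (pleiotropy test).

    β_GX is oriented non-negative first; weights are SE_GY⁻².  p values use
    the t distribution with n−2 df.
    """
    t = instruments.table
    if len(t) < 3:
        raise ValueError("MR-Egger needs >= 3 instruments")
    sign = np.sign(t["beta_gx"].to_numpy(float))
    sign[sign == 0] = 1.0
    x = t["beta_gx"].to_numpy(float) * sign
    y = t["beta_gy"].to_numpy(float) * sign
    w = 1.0 / t["se_gy"].to_numpy(float) ** 2
    X = np.column_stack([np.ones_like(x), x])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ coef
    dof = len(t) - 2
    sigma2 = float(np.sum(w * resid**2) / dof) if dof > 0 else 0.0
    # multiplicative over-dispersion, floored at 1 as in standard practice
    cov = np.linalg.inv(xtwx) * max(sigma2, 1.0)
    se_int, se_slope = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    p_slope = float(2 * stats.t.sf(abs(coef[1]) / se_slope, dof))
    p_int = float(2 * stats.t.sf(abs(coef[0]) / se_int, dof))
    return MREstimate(
        instruments.cpg_id,
        "egger",
        float(coef[1]),
        se_slope,
        p_slope,
        n_snps=len(t),
        egger_intercept=float(coef[0]),
        egger_intercept_se=se_int,
        egger_intercept_p=p_int,
    )


def weighted_median(
    instruments: InstrumentSet, n_boot: int = 1000, seed: int = 20240416
) -> MREstimate:
    """Weighted median of the ratio estimates; bootstrap SE.

    The estimate is the 50% point of the weighted empirical CDF of the
    sorted ratios (linear interpolation).  SE comes from a parametric
    bootstrap that redraws β_GX and β_GY from their sampling distributions
    (``n_boot`` replicates, fixed seed, recorded in the result metadata).
    """
    t = instruments.table
    if len(t) < 3:
        raise ValueError("weighted median needs >= 3 instruments")
    ratios, w = _ratio_weights(t)
    beta = _weighted_median_point(ratios, w)
    rng = np.random.default_rng(seed)
    bgx, segx = t["beta_gx"].to_numpy(float), t["se_gx"].to_numpy(float)
    bgy, segy = t["beta_gy"].to_numpy(float), t["se_gy"].to_numpy(float)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        gx = rng.normal(bgx, segx)
        gy = rng.normal(bgy, segy)
        gx[gx == 0] = np.finfo(float).tiny
        boots[b] = _weighted_median_point(gy / gx, (gx / segy) ** 2)
    se = float(boots.std(ddof=1))
    return MREstimate(
        instruments.cpg_id,
        "weighted_median",
        float(beta),
        se,
        _normal_p(beta, se),
        n_snps=len(t),
        meta={"n_boot": n_boot, "bootstrap_seed": seed},
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w  # midpoint rule
    cum /= w.sum()
    return float(np.interp(0.5, cum, r))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q values: q_(i) = min_{j≥i} p_(j)·m/j."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_epigenetic_mr(
    cpgs,
    mqtl_store: dict,
    gwas_store: dict,
    ld_store: dict | None = None,
    thresholds: SelectionThresholds | None = None,
    fdr_family: str = "pollutant",
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Per-CpG MR with routing, diagnostics, and within-family FDR.

    Routing: Wald ratio when exactly one instrument survives QC, IVW when
    two or more; Cochran's Q accompanies IVW, and MR-Egger plus the weighted
    median are added from three instruments.  ``fdr_family`` is "pollutant"
    (default) or "pooled".  CpGs without valid instruments stay in the output
    flagged, never silently dropped.
    """
    records = []
    for cpg in cpgs:
        rec = {
            "cpg": cpg.cpg_id, "chr": cpg.chrom, "pos": cpg.position,
            "gene": cpg.gene, "pollutant": cpg.pollutant,
            "method": "", "n_snps": 0, "beta": np.nan, "se": np.nan,
            "or": np.nan, "or_lcl": np.nan, "or_ucl": np.nan, "p": np.nan,
            "q": np.nan, "q_p": np.nan,
            "egger_intercept": np.nan, "egger_intercept_p": np.nan,
            "weighted_median_beta": np.nan, "weighted_median_p": np.nan,
            "flag": "",
        }
        mqtl = mqtl_store.get(cpg.cpg_id)
        gwas = gwas_store.get(cpg.cpg_id)
        if mqtl is None or gwas is None:
            rec["flag"] = "no summary statistics"
            records.append(rec)
            continue
        ld = (ld_store or {}).get(cpg.cpg_id)
        selected = select_instruments(mqtl, cpg, ld, thresholds)
        iset = harmonize(selected, gwas, cpg.cpg_id) if len(selected) else InstrumentSet(
            cpg.cpg_id, pd.DataFrame(), "no valid instruments"
        )
        if iset.n_snps == 0:
            rec["flag"] = "no valid instruments"
            records.append(rec)
            continue
        if iset.n_snps == 1:
            primary = wald_ratio(iset.table.iloc[0], cpg.cpg_id)
        else:
            primary = ivw(iset)
            rec["q"], rec["q_p"] = primary.q, primary.q_p
        rec.update(
            method=primary.method, n_snps=iset.n_snps, beta=primary.beta,
            se=primary.se, p=primary.p, **{"or": primary.odds_ratio},
            or_lcl=primary.or_ci[0], or_ucl=primary.or_ci[1],
        )
        if iset.n_snps >= 3:
            eg = egger(iset)
            rec["egger_intercept"] = eg.egger_intercept
            rec["egger_intercept_p"] = eg.egger_intercept_p
            wm = weighted_median(iset)
            rec["weighted_median_beta"] = wm.beta
            rec["weighted_median_p"] = wm.p
        records.append(rec)
    out = pd.DataFrame(records)
    out["fdr"] = np.nan
    ok = out["p"].notna()
    if fdr_family == "pollutant":
        for _, idx in out[ok].groupby("pollutant").groups.items():
            out.loc[idx, "fdr"] = bh_fdr(out.loc[idx, "p"])
    else:
        out.loc[ok, "fdr"] = bh_fdr(out.loc[ok, "p"])
    out["significant"] = out["fdr"] < fdr_level
    return out.sort_values("cpg").reset_index(drop=True)
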