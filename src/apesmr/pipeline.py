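"""End-to-end driver: simulate → cohort → MR → coloc → meta → interaction.

A :class:`RunConfig` (usually loaded from YAML) describes either input file
paths or a simulation block per data domain, plus every analysis threshold.
:func:`run_all` executes the stages in order, writes each stage's tables
under the output directory, and finishes with a manifest listing every
output file with its SHA-256 hash — identical config + seed reproduces
identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    compute_apes,
    derive_apes_weights,
    fit_cox,
    quartile_categories,
    trend_test,
)
from .coloc import ColocPriors, colocalize
from .interaction import fit_interaction, stratify_by_genotype
from .io import (
    file_sha256,
    read_cohort,
    read_summary_stats,
    write_cohort,
    write_summary_stats,
    write_truth,
)
from .meta import dersimonian_laird, forest_table, read_study_csv
from .mr import CpGSite, SelectionThresholds, run_epigenetic_mr
from .simulate import (
    MODEL1_COVARIATES,
    MODEL2_COVARIATES,
    POLLUTANTS,
    CohortConfig,
    RegionConfig,
    generate_ld_matrix,
    generate_meta_studies,
    generate_mqtl_summary,
    generate_outcome_gwas,
)

__all__ = ["RunConfig", "run_all", "load_config", "demo_config"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one reproducible run needs.

    For each data domain exactly one of {input path(s), simulation spec}
    must be given; thresholds default to the analysis conventions used
    throughout the package (instrument P < 1e-8, 1 Mb cis window, r² < 0.01,
    F ≥ 10, FDR 0.05, colocalization call at posterior ≥ 0.80, meta target
    increment 10 μg/m³).
    """

    outdir: str = "apesmr_out"
    seed: int = 0
    # cohort domain
    cohort_path: str | None = None
    survivor_path: str | None = None
    simulate_cohort: dict | None = None
    simulate_survivors: dict | None = None
    # summary-statistic domain
    mqtl_paths: dict | None = None  # cpg_id -> path
    gwas_paths: dict | None = None
    regions: list | None = None  # list of region spec dicts (simulation)
    # meta domain
    meta_path: str | None = None
    simulate_meta: dict | None = None
    # thresholds
    p_mqtl: float = 1e-8
    cis_window: int = 1_000_000
    r2_max: float = 0.01
    f_min: float = 10.0
    fdr_level: float = 0.05
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    pp4_threshold: float = 0.80
    target_increment: float = 10.0
    interaction_variants: list = field(default_factory=list)
    interaction_exposures: list = field(default_factory=list)
    # survivor analyses reuse the incidence-derived score weights by default
    reuse_apes_weights: bool = True
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.cohort_path is None) == (self.simulate_cohort is None):
            raise ValueError("give exactly one of cohort_path / simulate_cohort")
        if self.mqtl_paths is None and self.regions is None:
            raise ValueError("give mqtl_paths+gwas_paths or a regions simulation block")
        if self.meta_path is None and self.simulate_meta is None:
            raise ValueError("give meta_path or simulate_meta")
        for name in ("p_mqtl", "r2_max", "fdr_level", "pp4_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0,1]")
        if self.cis_window < 0 or self.f_min < 0 or self.target_increment <= 0:
            raise ValueError("cis_window/f_min must be >= 0 and target_increment > 0")

    def config_hash(self) -> str:
        def jsonable(x):
            if isinstance(x, dict):
                return {str(k): jsonable(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [jsonable(v) for v in x]
            return x if isinstance(x, (str, int, float, bool, type(None))) else str(x)

        blob = jsonable(dataclasses.asdict(self))
        # where outputs land and how chatty the log is do not change results
        blob.pop("outdir", None)
        blob.pop("log_level", None)
        return hashlib.sha256(
            json.dumps(blob, sort_keys=True).encode()
        ).hexdigest()[:16]


def demo_config(seed: int = 0, outdir: str = "apesmr_demo") -> RunConfig:
    """A fully simulated end-to-end run at desk scale.

    One incidence cohort (n=25,000, ~9% 13-year event rate so the joint
    four-pollutant weight fit is stable under the exposures' strong mutual
    correlation), one survivor cohort (n=2,500, ~25% mortality),
    three cis-regions with one strongly causal CpG, a 7-study meta-analysis
    with mixed reporting increments, and two variants carried into the
    interaction stage.
    """
    pollutant_betas = {"pm25": 0.10, "pm10": 0.02, "no2": 0.01, "nox": 0.003}
    return RunConfig(
        outdir=outdir,
        seed=seed,
        simulate_cohort=dict(
            n_participants=25_000,
            incidence_loghr={**pollutant_betas, "age": 0.03, "smoking": 0.2},
            variant_ids=("rs1", "rs2"),
            effect_allele_freqs=(0.30, 0.20),
            interaction_loghr={("rs1", "pm25"): 0.05},
            n_principal_components=10,
            weibull_scale=100.0,
        ),
        simulate_survivors=dict(
            n_participants=2_500,
            incidence_loghr={**pollutant_betas, "age": 0.05},
            variant_ids=("rs1", "rs2"),
            effect_allele_freqs=(0.30, 0.20),
            n_principal_components=10,
            weibull_scale=40.0,
        ),
        regions=[
            dict(
                cpg_id="cg0000001", cpg_chrom="2", cpg_position=1_000_000,
                variant_positions=(960_000, 990_000, 1_030_000),
                effect_allele_freqs=(0.30, 0.40, 0.25),
                mqtl_effects=(0.45, 0.05, 0.40), ld_decay=5e-5,
                causal_effect=1.2, pollutant="pm25", gene="GENE_A",
            ),
            dict(
                cpg_id="cg0000002", cpg_chrom="5", cpg_position=2_000_000,
                variant_positions=(1_950_000, 2_040_000),
                effect_allele_freqs=(0.35, 0.20),
                mqtl_effects=(0.50, 0.02), ld_decay=5e-5,
                causal_effect=0.0, pollutant="pm25", gene="GENE_B",
            ),
            dict(
                cpg_id="cg0000003", cpg_chrom="11", cpg_position=3_000_000,
                variant_positions=(2_990_000,),
                effect_allele_freqs=(0.25,),
                mqtl_effects=(0.55,), ld_decay=5e-5,
                causal_effect=0.0, pollutant="no2", gene="GENE_C",
            ),
        ],
        simulate_meta=dict(
            k=7, true_log_rr=0.35, tau2=0.05,
            ses=[0.10, 0.15, 0.20, 0.12, 0.25, 0.18, 0.08],
            increments=[10, 10, 5, 10, 5, 10, 10],
        ),
        interaction_variants=["rs1", "rs2"],
        interaction_exposures=["pm25"],
    )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _metadata(cfg: RunConfig) -> dict:
    return {"package": f"apesmr {__version__}", "seed": cfg.seed, "config": cfg.config_hash()}


def _seed_for(cfg: RunConfig, stage: str) -> int:
    # stable per-stage substream, kept below 2**31
    digest = hashlib.sha256(f"{cfg.seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _cohort_stage(cfg: RunConfig, outdir: Path, outputs: list) -> tuple:
    if cfg.simulate_cohort is not None:
        spec = dict(cfg.simulate_cohort)
        spec.setdefault("seed", _seed_for(cfg, "cohort"))
        ccfg = CohortConfig(**spec)
        from .simulate import generate_cohort

        cohort = generate_cohort(ccfg)
        write_cohort(cohort, outdir / "cohort.csv", _metadata(cfg))
        write_truth(
            {"incidence_loghr": ccfg.incidence_loghr,
             "interaction_loghr": {f"{k[0]}*{k[1]}": v for k, v in ccfg.interaction_loghr.items()},
             "seed": ccfg.seed},
            outdir / "cohort_truth.json",
        )
        outputs += [outdir / "cohort.csv", outdir / "cohort_truth.json"]
    else:
        cohort = read_cohort(cfg.cohort_path)

    survivors = None
    if cfg.simulate_survivors is not None:
        spec = dict(cfg.simulate_survivors)
        spec.setdefault("seed", _seed_for(cfg, "survivors"))
        scfg = CohortConfig(**spec)
        from .simulate import generate_cohort

        survivors = generate_cohort(scfg)
        write_cohort(survivors, outdir / "survivors.csv", _metadata(cfg))
        outputs.append(outdir / "survivors.csv")
    elif cfg.survivor_path is not None:
        survivors = read_cohort(cfg.survivor_path)
    return cohort, survivors


def _epi_tables(cohort: pd.DataFrame, label: str, weights=None) -> pd.DataFrame:
    """Per-pollutant quartile/trend/per-increment rows plus the per-SD score row.

    ``weights`` lets the caller reuse score weights derived in another cohort
    (the default for survivor analyses, which are typically too small to
    re-derive a stable joint four-pollutant fit).
    """
    if weights is None:
        weights = derive_apes_weights(cohort)
    score = compute_apes(cohort, weights)
    df = cohort.copy()
    df["apes_std"] = score["apes_std"]
    rows = []
    for pol in POLLUTANTS:
        cats, cuts = quartile_categories(df[pol])
        df["_cat"] = cats
        for q in (2, 3, 4):
            df[f"_q{q}"] = (cats == q).astype(int)
        fit = fit_cox(df, [f"_q{q}" for q in (2, 3, 4)] + list(MODEL2_COVARIATES))
        for q in (2, 3, 4):
            term = f"_q{q}"
            rows.append(
                {"exposure": pol, "contrast": f"Q{q} vs Q1", "hr": fit.hr(term),
                 "lcl": np.exp(fit.ci(term)[0]), "ucl": np.exp(fit.ci(term)[1]),
                 "p": fit.p(term)}
            )
        rows.append(
            {"exposure": pol, "contrast": "P for trend", "hr": np.nan,
             "lcl": np.nan, "ucl": np.nan,
             "p": trend_test(df, cats)}
        )
        df["_per5"] = df[pol] / 5.0
        fit5 = fit_cox(df, ["_per5"] + list(MODEL2_COVARIATES))
        rows.append(
            {"exposure": pol, "contrast": "per 5 ug/m3", "hr": fit5.hr("_per5"),
             "lcl": np.exp(fit5.ci("_per5")[0]), "ucl": np.exp(fit5.ci("_per5")[1]),
             "p": fit5.p("_per5")}
        )
    fit_apes = fit_cox(df, ["apes_std"] + list(MODEL2_COVARIATES))
    rows.append(
        {"exposure": "apes", "contrast": "per SD", "hr": fit_apes.hr("apes_std"),
         "lcl": np.exp(fit_apes.ci("apes_std")[0]), "ucl": np.exp(fit_apes.ci("apes_std")[1]),
         "p": fit_apes.p("apes_std")}
    )
    out = pd.DataFrame(rows)
    out.insert(0, "outcome", label)
    return out


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage and return the output manifest.

    Stage order: simulate (if configured) → cohort incidence (+ survivor)
    analyses → per-CpG MR → colocalization of the FDR-significant CpGs →
    meta-analysis → interaction models.  A stage failure raises with the
    stage name; files already written stay on disk.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    meta_header = _metadata(cfg)

    stage = "cohort"
    try:
        cohort, survivors = _cohort_stage(cfg, outdir, outputs)
        incidence_weights = derive_apes_weights(cohort)
        epi = _epi_tables(cohort, "incidence", weights=incidence_weights)
        if survivors is not None:
            survivor_weights = (
                incidence_weights if cfg.reuse_apes_weights
                else derive_apes_weights(survivors)
            )
            epi = pd.concat(
                [epi, _epi_tables(survivors, "survival", weights=survivor_weights)],
                ignore_index=True,
            )
        path = outdir / "cohort_estimates.tsv"
        with open(path, "w") as fh:
            fh.write("".join(f"# {k}={v}\n" for k, v in meta_header.items()))
            epi.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        outputs.append(path)

        stage = "mr"
        cpgs, mqtl_store, gwas_store, ld_store = _summary_stage(cfg, outdir, outputs)
        thresholds = SelectionThresholds(cfg.p_mqtl, cfg.cis_window, cfg.r2_max, cfg.f_min)
        mr_table = run_epigenetic_mr(
            cpgs, mqtl_store, gwas_store, ld_store, thresholds, fdr_level=cfg.fdr_level
        )
        path = outdir / "mr_estimates.tsv"
        with open(path, "w") as fh:
            fh.write("".join(f"# {k}={v}\n" for k, v in meta_header.items()))
            mr_table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        outputs.append(path)

        stage = "coloc"
        priors = ColocPriors(cfg.coloc_p1, cfg.coloc_p2, cfg.coloc_p12)
        coloc_rows = []
        for cpg_id in sorted(mr_table.loc[mr_table["significant"], "cpg"]):
            res = colocalize(
                mqtl_store[cpg_id], gwas_store[cpg_id], priors, cfg.pp4_threshold
            )
            row = {"cpg": cpg_id, **res.posteriors,
                   "lead_variant": res.lead_variant, "lead_share": res.lead_share,
                   "colocalized": res.decision}
            coloc_rows.append(row)
        coloc_df = pd.DataFrame(
            coloc_rows,
            columns=["cpg", "PP0", "PP1", "PP2", "PP3", "PP4",
                     "lead_variant", "lead_share", "colocalized"],
        )
        path = outdir / "coloc_results.tsv"
        with open(path, "w") as fh:
            fh.write("".join(f"# {k}={v}\n" for k, v in meta_header.items()))
            coloc_df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        outputs.append(path)

        stage = "meta"
        if cfg.simulate_meta is not None:
            spec = dict(cfg.simulate_meta)
            spec.setdefault("seed", _seed_for(cfg, "meta"))
            studies = generate_meta_studies(**spec)
        else:
            studies = read_study_csv(cfg.meta_path)
        result = dersimonian_laird(studies, cfg.target_increment)
        forest = forest_table(result, studies)
        path = outdir / "meta_forest.tsv"
        with open(path, "w") as fh:
            fh.write("".join(f"# {k}={v}\n" for k, v in meta_header.items()))
            fh.write(
                f"# pooled_rr={result.pooled_rr:.6g} tau2={result.tau2:.6g} "
                f"I2={result.i2:.4g} Q={result.q:.6g} p={result.p:.3g}\n"
            )
            forest.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        outputs.append(path)

        stage = "interaction"
        inter_rows = []
        variants = cfg.interaction_variants or [
            c for c in cohort.columns if c.startswith("rs")
        ]
        exposures = cfg.interaction_exposures or ["pm25"]
        n_pcs = sum(c.startswith("pc") for c in cohort.columns)
        for variant in variants:
            for exposure in exposures:
                res = fit_interaction(cohort, variant, exposure, n_pcs=n_pcs)
                strata = stratify_by_genotype(cohort, variant, exposure, n_pcs=n_pcs)
                row = {
                    "variant": variant, "exposure": exposure,
                    "interaction_hr": res.interaction_hr,
                    "lcl": res.interaction_ci[0], "ucl": res.interaction_ci[1],
                    "p": res.interaction_p,
                }
                for d in (0, 1, 2):
                    row[f"hr_dosage{d}"] = (
                        strata[d].hr(exposure) if d in strata else np.nan
                    )
                inter_rows.append(row)
        path = outdir / "interaction_estimates.tsv"
        with open(path, "w") as fh:
            fh.write("".join(f"# {k}={v}\n" for k, v in meta_header.items()))
            pd.DataFrame(inter_rows).to_csv(fh, sep="\t", index=False, float_format="%.6g")
        outputs.append(path)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package": f"apesmr {__version__}",
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "files": {p.name: file_sha256(p) for p in sorted(outputs)},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _summary_stage(cfg: RunConfig, outdir: Path, outputs: list) -> tuple:
    """Load or simulate per-CpG mQTL and outcome summary statistics."""
    cpgs, mqtl_store, gwas_store, ld_store = [], {}, {}, {}
    if cfg.regions is not None:
        for i, spec in enumerate(cfg.regions):
            spec = dict(spec)
            pollutant = spec.pop("pollutant", "pm25")
            gene = spec.pop("gene", "")
            spec.setdefault("seed", _seed_for(cfg, f"region{i}"))
            region = RegionConfig(**spec)
            ld = generate_ld_matrix(
                region.n_variants, region.ld_decay, region.variant_positions
            )
            mqtl = generate_mqtl_summary(region, ld)
            gwas = generate_outcome_gwas(region, ld)
            cpgs.append(
                CpGSite(region.cpg_id, region.cpg_chrom, region.cpg_position,
                        gene=gene, pollutant=pollutant)
            )
            mqtl_store[region.cpg_id] = mqtl
            gwas_store[region.cpg_id] = gwas
            ld_store[region.cpg_id] = ld
            mq_path = outdir / f"mqtl_{region.cpg_id}.tsv"
            gw_path = outdir / f"gwas_{region.cpg_id}.tsv"
            write_summary_stats(mqtl, mq_path, _metadata(cfg))
            write_summary_stats(gwas, gw_path, _metadata(cfg))
            outputs += [mq_path, gw_path]
            write_truth(
                {"cpg": region.cpg_id, "causal_effect": region.causal_effect,
                 "mqtl_effects": list(region.mqtl_effects), "seed": region.seed},
                outdir / f"truth_{region.cpg_id}.json",
            )
            outputs.append(outdir / f"truth_{region.cpg_id}.json")
    else:
        for cpg_id, path in cfg.mqtl_paths.items():
            mqtl_store[cpg_id] = read_summary_stats(path)
            gwas_store[cpg_id] = read_summary_stats(cfg.gwas_paths[cpg_id])
            first = mqtl_store[cpg_id].iloc[0]
            cpgs.append(CpGSite(cpg_id, str(first["CHR"]), int(first["POS"])))
    return cpgs, mqtl_store, gwas_store, ld_store
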