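"""MR engine: instrument QC, harmonization, the four estimators, FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from apesmr import (
    CpGSite,
    InstrumentSet,
    SelectionThresholds,
    bh_fdr,
    cochran_q,
    compute_f_statistic,
    egger,
    harmonize,
    ivw,
    run_epigenetic_mr,
    select_instruments,
    wald_ratio,
    weighted_median,
)

from .conftest import make_sumstats


def brute_force_selection(mqtl, cpg, ld, th):
    """Spec-rule enumeration written independently of the implementation:
    cis+significant filter, then greedy ascending-p LD pruning, then the
    weak-instrument F cut."""
    rows = []
    for i in range(len(mqtl)):
        r = mqtl.iloc[i]
        if str(r["CHR"]) != str(cpg.chrom):
            continue
        if abs(r["POS"] - cpg.position) > th.cis_window:
            continue
        if not r["P"] < th.p_max:
            continue
        rows.append(i)
    rows.sort(key=lambda i: (mqtl.iloc[i]["P"], mqtl.iloc[i]["SNP"]))
    kept = []
    for i in rows:
        ok = True
        for j in kept:
            if ld[i, j] ** 2 >= th.r2_max:
                ok = False
        if ok:
            kept.append(i)
    survivors = []
    for i in kept:
        r = mqtl.iloc[i]
        if (r["BETA"] / r["SE"]) ** 2 >= th.f_min:
            survivors.append(r["SNP"])
    return sorted(survivors)


class TestSelection:
    cpg = CpGSite("cg1", "1", 1_000_000)

    def test_enumerated_toy_panel_matches_oracle(self):
        # five cis variants; p values force the greedy order 5,4,1,2,3 and the
        # LD matrix knocks out the second-ranked variant
        p = np.array([1e-9, 1e-9, 1e-7, 1e-10, 1e-12])
        z = np.abs(np.array([6.1, 6.2, 5.3, 6.5, 7.0]))
        ses = np.full(5, 0.05)
        betas = z * ses
        df = make_sumstats([f"v{i}" for i in range(5)], betas, ses,
                           pos=[990_000, 995_000, 1_000_000, 1_005_000, 1_010_000])
        df["P"] = p
        ld = np.eye(5)
        ld[0, 1] = ld[1, 0] = np.sqrt(0.5)  # v0-v1 r2 = 0.5
        ld[3, 4] = ld[4, 3] = np.sqrt(0.3)  # v3-v4 r2 = 0.3
        th = SelectionThresholds()
        got = sorted(select_instruments(df, self.cpg, ld, th)["SNP"])
        want = brute_force_selection(df, self.cpg, ld, th)
        assert got == want
        # hand enumeration: v4 kept (best p), v3 dropped (r2 .3 with v4),
        # v0 and v1 both significant but mutually linked -> only v0 kept
        # (lower rank by p tie -> SNP id tie-break), v2 fails p threshold
        assert got == ["v0", "v4"]

    def test_random_panels_match_oracle(self, rng):
        for _ in range(20):
            k = 8
            pos = np.sort(rng.choice(np.arange(1, 2_200_000), k, replace=False))
            ses = np.full(k, 0.04)
            betas = rng.normal(0, 0.35, k)
            df = make_sumstats([f"s{i}" for i in range(k)], betas, ses, pos=list(pos))
            corr = np.eye(k)
            for i in range(k):
                for j in range(i + 1, k):
                    corr[i, j] = corr[j, i] = rng.random() * 0.5
            th = SelectionThresholds(p_max=1e-3, r2_max=0.05, f_min=10)
            got = sorted(select_instruments(df, self.cpg, corr, th)["SNP"])
            assert got == brute_force_selection(df, self.cpg, corr, th)

    def test_exact_1mb_boundary_inclusive(self):
        df = make_sumstats(["edge"], [0.5], [0.05], pos=[2_000_000])
        got = select_instruments(df, self.cpg, None, SelectionThresholds())
        assert list(got["SNP"]) == ["edge"]
        df2 = make_sumstats(["out"], [0.5], [0.05], pos=[2_000_001])
        assert select_instruments(df2, self.cpg, None, SelectionThresholds()).empty

    def test_all_weak_p_gives_empty_set(self):
        df = make_sumstats(["a", "b"], [0.2, 0.2], [0.04, 0.04], pos=[999_000, 1_001_000])
        df["P"] = 1e-6
        assert select_instruments(df, self.cpg, None, SelectionThresholds()).empty


class TestFStatistic:
    def test_direct_arithmetic(self):
        assert compute_f_statistic(0.5, 0.05) == pytest.approx(100.0)
        assert compute_f_statistic(0.0, 0.1) == 0.0

    def test_threshold_matches_z_boundary(self):
        z = np.sqrt(10.0)
        assert compute_f_statistic(z * 0.01, 0.01) == pytest.approx(10.0)

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            compute_f_statistic(0.5, 0.0)


class TestHarmonize:
    def test_swapped_alleles_flip_sign(self):
        exp = make_sumstats(["v"], [0.3], [0.03], ea="A", oa="G")
        out = make_sumstats(["v"], [-0.2], [0.05], ea="G", oa="A")
        iset = harmonize(exp, out)
        assert iset.table["beta_gy"].iloc[0] == pytest.approx(0.2)

    def test_strand_flip_resolved(self):
        exp = make_sumstats(["v"], [0.3], [0.03], ea="A", oa="G")
        out = make_sumstats(["v"], [0.2], [0.05], ea="T", oa="C")
        iset = harmonize(exp, out)
        assert iset.table["beta_gy"].iloc[0] == pytest.approx(0.2)

    def test_palindromic_midrange_dropped(self):
        exp = make_sumstats(["v"], [0.3], [0.03], ea="A", oa="T", eaf=0.50)
        out = make_sumstats(["v"], [0.2], [0.05], ea="A", oa="T", eaf=0.50)
        iset = harmonize(exp, out)
        assert iset.n_snps == 0
        assert iset.flag == "no valid instruments"

    def test_palindromic_clear_frequency_aligned(self):
        exp = make_sumstats(["v"], [0.3], [0.03], ea="A", oa="T", eaf=0.10)
        out = make_sumstats(["v"], [0.2], [0.05], ea="A", oa="T", eaf=0.88)
        iset = harmonize(exp, out)
        # frequencies disagree -> the outcome effect allele is the other one
        assert iset.table["beta_gy"].iloc[0] == pytest.approx(-0.2)

    def test_incompatible_alleles_dropped(self):
        exp = make_sumstats(["v"], [0.3], [0.03], ea="A", oa="G")
        out = make_sumstats(["v"], [0.2], [0.05], ea="A", oa="C")
        assert harmonize(exp, out).n_snps == 0


class TestWaldRatio:
    row = {"beta_gx": 0.5, "se_gx": 0.05, "beta_gy": 0.1, "se_gy": 0.05}

    def test_hand_example(self):
        est = wald_ratio(self.row)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)
        assert est.odds_ratio == pytest.approx(np.exp(0.2))

    def test_zero_outcome_gives_null(self):
        est = wald_ratio({**self.row, "beta_gy": 0.0})
        assert est.beta == 0.0
        assert est.odds_ratio == 1.0

    def test_scale_invariance(self):
        est1 = wald_ratio(self.row)
        est2 = wald_ratio({**self.row, "beta_gx": 1.0, "beta_gy": 0.2})
        assert est1.beta == pytest.approx(est2.beta)

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio({**self.row, "beta_gx": 0.0})


class TestIVW:
    def test_hand_computed_example(self, two_instrument_set):
        est = ivw(two_instrument_set)
        assert est.beta == pytest.approx(0.18, abs=1e-12)
        assert est.se == pytest.approx(1 / np.sqrt(500), abs=1e-12)

    def test_equals_zero_intercept_weighted_regression(self, rng):
        # the ratio-weighted mean form must match WLS of beta_gy on beta_gx
        # with weights se_gy^-2 and no intercept, on random instances
        import statsmodels.api as sm

        for _ in range(10):
            k = rng.integers(2, 12)
            t = pd.DataFrame(
                {
                    "SNP": [f"s{i}" for i in range(k)],
                    "beta_gx": rng.normal(0.3, 0.1, k),
                    "se_gx": np.full(k, 0.01),
                    "beta_gy": rng.normal(0.05, 0.03, k),
                    "se_gy": rng.uniform(0.01, 0.05, k),
                    "ea": "A",
                    "f_stat": 100.0,
                }
            )
            est = ivw(InstrumentSet("cg", t))
            wls = sm.WLS(t["beta_gy"], t[["beta_gx"]], weights=1 / t["se_gy"] ** 2).fit()
            assert est.beta == pytest.approx(float(wls.params.iloc[0]), abs=1e-10)

    def test_identical_ratios_give_zero_q(self):
        t = pd.DataFrame(
            {"SNP": ["a", "b"], "beta_gx": [0.2, 0.4], "se_gx": [0.01, 0.01],
             "beta_gy": [0.05, 0.10], "se_gy": [0.02, 0.02], "ea": "A",
             "f_stat": [400.0, 1600.0]}
        )
        est = ivw(InstrumentSet("cg", t))
        assert est.beta == pytest.approx(0.25)
        assert est.q == pytest.approx(0.0, abs=1e-12)
        assert est.q_p == pytest.approx(1.0)

    def test_single_instrument_rejected(self, two_instrument_set):
        solo = InstrumentSet("cg", two_instrument_set.table.iloc[:1])
        with pytest.raises(ValueError, match="wald"):
            ivw(solo)
        est = wald_ratio(solo.table.iloc[0])
        assert est.beta == pytest.approx(0.2)


class TestCochranQ:
    def test_hand_computation(self, two_instrument_set):
        q, df, p = cochran_q(two_instrument_set, 0.18)
        assert q == pytest.approx(0.8, abs=1e-12)
        assert df == 1

    def test_null_simulation_q_over_df_near_one(self, rng):
        qs = []
        for _ in range(200):
            k = 10
            bgx = rng.normal(0.4, 0.05, k)
            se_gy = np.full(k, 0.02)
            bgy = 0.1 * bgx + rng.normal(0, se_gy)
            t = pd.DataFrame(
                {"SNP": [f"s{i}" for i in range(k)], "beta_gx": bgx,
                 "se_gx": 0.001, "beta_gy": bgy, "se_gy": se_gy, "ea": "A",
                 "f_stat": 1e4}
            )
            est = ivw(InstrumentSet("cg", t))
            qs.append(est.q / est.q_df)
        assert np.mean(qs) == pytest.approx(1.0, abs=0.1)


class TestEgger:
    def test_exact_interpolation(self):
        x = np.array([0.2, 0.4, 0.6])
        t = pd.DataFrame(
            {"SNP": ["a", "b", "c"], "beta_gx": x, "se_gx": 0.01,
             "beta_gy": 0.05 + 0.3 * x, "se_gy": 0.02, "ea": "A", "f_stat": 100.0}
        )
        est = egger(InstrumentSet("cg", t))
        assert est.beta == pytest.approx(0.3, abs=1e-10)
        assert est.egger_intercept == pytest.approx(0.05, abs=1e-10)

    def test_directional_pleiotropy_recovered(self, rng):
        intercepts = []
        for _ in range(100):
            k = 20
            bgx = rng.uniform(0.2, 0.6, k)
            se_gy = np.full(k, 0.02)
            bgy = 0.1 + 0.2 * bgx + rng.normal(0, se_gy)
            t = pd.DataFrame(
                {"SNP": [f"s{i}" for i in range(k)], "beta_gx": bgx,
                 "se_gx": 0.001, "beta_gy": bgy, "se_gy": se_gy, "ea": "A",
                 "f_stat": 1e4}
            )
            intercepts.append(egger(InstrumentSet("cg", t)).egger_intercept)
        assert np.mean(intercepts) == pytest.approx(0.1, abs=0.01)

    def test_too_few_instruments_rejected(self, two_instrument_set):
        with pytest.raises(ValueError):
            egger(two_instrument_set)


class TestWeightedMedian:
    def make(self, ratios, weights):
        ratios = np.asarray(ratios, float)
        w = np.asarray(weights, float)
        se_gy = 1.0 / np.sqrt(w)  # with beta_gx = 1, weight = se_gy^-2
        return InstrumentSet(
            "cg",
            pd.DataFrame(
                {"SNP": [f"s{i}" for i in range(len(ratios))],
                 "beta_gx": 1.0, "se_gx": 1e-6, "beta_gy": ratios,
                 "se_gy": se_gy, "ea": "A", "f_stat": 1e12}
            ),
        )

    def test_symmetric_equal_weights(self):
        est = weighted_median(self.make([0.1, 0.2, 0.3], [1, 1, 1]))
        assert est.beta == pytest.approx(0.2, abs=1e-9)

    def test_dominant_weight_wins(self):
        est = weighted_median(self.make([0.1, 0.9, 0.3], [1e6, 1.0, 1.0]))
        assert est.beta == pytest.approx(0.1, abs=0.01)

    def test_bootstrap_se_reproducible(self):
        iset = self.make([0.1, 0.25, 0.3, 0.15], [1, 2, 1, 2])
        a = weighted_median(iset)
        b = weighted_median(iset)
        assert a.se == b.se
        assert a.meta["n_boot"] == 1000


class TestBHFDR:
    def test_hand_computed_step_up(self):
        q = bh_fdr([0.001, 0.01, 0.02, 0.8])
        assert np.allclose(q, [0.004, 0.02, 4 * 0.02 / 3, 0.8], atol=1e-12)

    def test_all_equal_p_unchanged(self):
        assert np.allclose(bh_fdr([0.3, 0.3, 0.3]), 0.3)

    def test_single_p_identity(self):
        assert bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_empty_input(self):
        assert bh_fdr([]).size == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


@given(
    st.lists(
        st.tuples(st.floats(0.1, 1.0), st.floats(-0.3, 0.3), st.floats(0.01, 0.1)),
        min_size=2,
        max_size=15,
    )
)
def test_ivw_two_form_equivalence_property(rows):
    """Ratio-weighted mean and zero-intercept WLS agree to 1e-10."""
    t = pd.DataFrame(
        {"SNP": [f"s{i}" for i in range(len(rows))],
         "beta_gx": [r[0] for r in rows], "se_gx": 0.01,
         "beta_gy": [r[1] for r in rows], "se_gy": [r[2] for r in rows],
         "ea": "A", "f_stat": 100.0}
    )
    est = ivw(InstrumentSet("cg", t))
    x = t["beta_gx"].to_numpy()
    y = t["beta_gy"].to_numpy()
    w = 1.0 / t["se_gy"].to_numpy() ** 2
    wls_slope = np.sum(w * x * y) / np.sum(w * x * x)
    assert est.beta == pytest.approx(wls_slope, abs=1e-10)
    # Q = 0 iff all ratio estimates coincide
    ratios = y / x
    if est.q < 1e-12:
        assert np.ptp(ratios) < 1e-5


class TestRunEpigeneticMR:
    def _stores(self, rng, n_cpg=4, causal=(0,), theta=0.5):
        from apesmr import RegionConfig, generate_ld_matrix, generate_mqtl_summary, generate_outcome_gwas

        cpgs, mq, gw, lds = [], {}, {}, {}
        for i in range(n_cpg):
            cid = f"cg{i:06d}"
            k = 3
            pos = tuple(1_000_000 + 40_000 * j for j in range(k))
            region = RegionConfig(
                cpg_id=cid, cpg_chrom="1", cpg_position=1_020_000,
                variant_positions=pos, effect_allele_freqs=(0.3, 0.4, 0.35),
                mqtl_effects=(0.4, 0.35, 0.3), ld_decay=1e-3,
                causal_effect=theta if i in causal else 0.0,
                seed=int(rng.integers(2**31)),
            )
            ld = generate_ld_matrix(k, region.ld_decay, pos)
            cpgs.append(CpGSite(cid, "1", 1_020_000, pollutant="pm25"))
            mq[cid] = generate_mqtl_summary(region, ld)
            gw[cid] = generate_outcome_gwas(region, ld)
            lds[cid] = ld
        return cpgs, mq, gw, lds

    def test_routing_and_flags(self, rng):
        cpgs, mq, gw, lds = self._stores(rng)
        # starve one CpG of instruments by nuking its p values
        mq[cpgs[-1].cpg_id]["P"] = 0.5
        table = run_epigenetic_mr(cpgs, mq, gw, lds)
        assert len(table) == len(cpgs)
        starved = table[table["cpg"] == cpgs[-1].cpg_id].iloc[0]
        assert starved["flag"] == "no valid instruments"
        fitted = table[table["flag"] == ""]
        assert set(fitted["method"]) <= {"wald_ratio", "ivw"}
        single = fitted[fitted["n_snps"] == 1]
        assert (single["method"] == "wald_ratio").all()

    def test_causal_cpg_flagged_null_not(self, rng):
        cpgs, mq, gw, lds = self._stores(rng, n_cpg=6, causal=(0,), theta=0.8)
        table = run_epigenetic_mr(cpgs, mq, gw, lds)
        row = table[table["cpg"] == "cg000000"].iloc[0]
        assert bool(row["significant"])
        assert table["fdr"].ge(table["p"] - 1e-15).all()
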