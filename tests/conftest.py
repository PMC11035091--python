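import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240416)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort with a planted PM2.5 effect, reused across tests."""
    from apesmr import CohortConfig, generate_cohort

    cfg = CohortConfig(
        n_participants=4000,
        incidence_loghr={"pm25": 0.10, "age": 0.03},
        variant_ids=("rs1",),
        effect_allele_freqs=(0.3,),
        weibull_scale=100.0,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture
def two_instrument_set():
    """The worked two-instrument example used for IVW/Q hand checks."""
    from apesmr import InstrumentSet

    table = pd.DataFrame(
        {
            "SNP": ["v1", "v2"],
            "beta_gx": [0.4, 0.2],
            "se_gx": [0.01, 0.01],
            "beta_gy": [0.08, 0.02],
            "se_gy": [0.02, 0.02],
            "ea": ["A", "A"],
            "f_stat": [1600.0, 400.0],
        }
    )
    return InstrumentSet("cg_demo", table)


def make_sumstats(snps, betas, ses, pos=None, ea="A", oa="G", eaf=0.3, chrom="1", n=10000):
    """Helper to build small summary-statistic frames."""
    from scipy import stats as st

    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    k = len(snps)
    return pd.DataFrame(
        {
            "SNP": snps,
            "CHR": chrom,
            "POS": pos if pos is not None else np.arange(1, k + 1) * 1000,
            "EA": ea if isinstance(ea, list) else [ea] * k,
            "OA": oa if isinstance(oa, list) else [oa] * k,
            "EAF": eaf if isinstance(eaf, list) else [eaf] * k,
            "BETA": betas,
            "SE": ses,
            "P": 2 * st.norm.sf(np.abs(betas / ses)),
            "N": n,
        }
    )
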