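"""Bayesian colocalization of two association signals in one region.

Tests whether two traits (here: CpG methylation and disease risk) share a
single causal variant, assuming at most one causal variant per trait.
Per-variant evidence is the Wakefield approximate Bayes factor

    log ABF = ½·log(1−r) + z²·r/2,   r = W/(V+W),  z = β/SE,  V = SE²

and the five hypotheses are scored by summing ABF products over causal
configurations:

    H0  no association with either trait
    H1  causal variant for trait 1 only
    H2  causal variant for trait 2 only
    H3  two distinct causal variants
    H4  one shared causal variant

All accumulation happens in log space with max-subtraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = ["ColocPriors", "ColocResult", "wakefield_abf", "colocalize", "per_snp_h4"]


@dataclass
class ColocPriors:
    """Per-variant prior probabilities and prior effect scales.

    ``p1``/``p2``: a variant is causal for trait 1 / trait 2 only;
    ``p12``: causal for both.  ``sd1`` is the prior effect SD on the
    quantitative (SD-methylation) scale, ``sd2`` on the log-odds scale.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    sd1: float = 0.15
    sd2: float = 0.2

    def validate(self) -> None:
        for name in ("p1", "p2", "p12"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0,1)")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("p1 + p2 + p12 must be < 1")
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise ValueError("prior effect SDs must be > 0")


@dataclass
class ColocResult:
    posteriors: dict  # {"PP0": ..., ..., "PP4": ...}
    snp_h4: pd.Series  # per-variant posterior of being THE shared variant | H4
    lead_variant: str
    lead_share: float
    pp4_threshold: float = 0.80
    n_variants: int = 0

    @property
    def decision(self) -> bool:
        """Colocalization call: PP4 and the lead variant's H4 share both ≥ threshold."""
        return (
            self.posteriors["PP4"] >= self.pp4_threshold
            and self.lead_share >= self.pp4_threshold
        )


def wakefield_abf(beta: float, se: float, prior_sd: float) -> float:
    """Log approximate Bayes factor for one variant-trait association."""
    if se <= 0:
        raise ValueError("SE must be > 0")
    if prior_sd <= 0:
        raise ValueError("prior SD must be > 0")
    v, w = se**2, prior_sd**2
    r = w / (v + w)
    z = beta / se
    return 0.5 * math.log1p(-r) + 0.5 * z * z * r


def colocalize(
    trait1: pd.DataFrame,
    trait2: pd.DataFrame,
    priors: ColocPriors | None = None,
    pp4_threshold: float = 0.80,
) -> ColocResult:
    """Posterior probabilities of the five sharing hypotheses.

    ``trait1``/``trait2`` are summary-statistics frames with SNP/BETA/SE
    columns; the variant intersection is analysed.  Sums over configurations
    use the standard single-causal-variant identities: with per-variant log
    ABFs l1, l2,

        H1 ∝ p1·Σᵢ ABF1ᵢ,  H2 ∝ p2·Σⱼ ABF2ⱼ,
        H4 ∝ p12·Σᵢ ABF1ᵢ·ABF2ᵢ,  H3 ∝ p1p2·(Σᵢ Σⱼ − Σᵢ₌ⱼ) ABF1ᵢ·ABF2ⱼ.
    """
    priors = priors or ColocPriors()
    priors.validate()
    t1 = trait1.set_index("SNP")
    t2 = trait2.set_index("SNP")
    snps = t1.index.intersection(t2.index)
    if len(snps) == 0:
        raise ValueError("no shared variants between the two traits")
    l1 = np.array([wakefield_abf(t1.loc[s, "BETA"], t1.loc[s, "SE"], priors.sd1) for s in snps])
    l2 = np.array([wakefield_abf(t2.loc[s, "BETA"], t2.loc[s, "SE"], priors.sd2) for s in snps])

    lsum1 = logsumexp(l1)
    lsum2 = logsumexp(l2)
    lsum12 = logsumexp(l1 + l2)
    lh0 = 0.0
    lh1 = math.log(priors.p1) + lsum1
    lh2 = math.log(priors.p2) + lsum2
    # all ordered pairs minus the diagonal, in log space
    pair_all = lsum1 + lsum2
    with np.errstate(divide="ignore"):
        diff = 1.0 - math.exp(lsum12 - pair_all)
        lh3 = (
            math.log(priors.p1) + math.log(priors.p2) + pair_all + math.log(diff)
            if diff > 0
            else -np.inf
        )
    lh4 = math.log(priors.p12) + lsum12

    lh = np.array([lh0, lh1, lh2, lh3, lh4])
    post = np.exp(lh - logsumexp(lh))
    post /= post.sum()
    posteriors = {f"PP{i}": float(post[i]) for i in range(5)}

    snp_post = np.exp((l1 + l2) - lsum12)
    snp_post /= snp_post.sum()
    snp_h4 = pd.Series(snp_post, index=snps).sort_values(ascending=False)
    return ColocResult(
        posteriors=posteriors,
        snp_h4=snp_h4,
        lead_variant=str(snp_h4.index[0]),
        lead_share=float(snp_h4.iloc[0]),
        pp4_threshold=pp4_threshold,
        n_variants=len(snps),
    )


def per_snp_h4(result: ColocResult) -> pd.Series:
    """Per-variant shared-causal posteriors ranked descending.

    Empty (with the result flagged by the caller) when the H4 hypothesis
    carries no mass.
    """
    if result.posteriors["PP4"] <= 0:
        return pd.Series(dtype=float)
    return result.snp_h4
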