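"""Approximate-Bayes-factor colocalization under a single-causal-variant model.

For each instrument region, compares five hypotheses about a pair of
traits (metabolite level and age at menarche/menopause):

* H0 - no causal variant for either trait in the region,
* H1 - a causal variant for the outcome only,
* H2 - a causal variant for the metabolite only,
* H3 - distinct causal variants for the two traits,
* H4 - one shared causal variant.

Per-SNP evidence is the Wakefield approximate Bayes factor computed
from beta and its standard error with a N(0, prior_sd^2) effect prior
(prior_sd = 0.15, the quantitative-trait convention).  Hypothesis
likelihoods are sums of ABF products over causal-variant
configurations, weighted by the per-configuration priors p1, p2 and
p12, and normalized in log space.  A metabolite is called colocalized
when the H4 posterior exceeds the threshold (default 0.8) in at least
one of its instrument regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import InputError
from .summary_io import SummaryStats, harmonize

DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5
DEFAULT_PRIOR_SD = 0.15
DEFAULT_HALF_WIDTH = 500_000   # +/-500 kb: a 1 Mb total span around the lead
DEFAULT_MAF_MIN = 0.01
H4_THRESHOLD = 0.8


@dataclass
class Region:
    """One trait's summary statistics within a window around a lead SNP."""

    lead: str
    trait: str
    df: pd.DataFrame  # snp, pos, beta, se, maf
    half_width: int = DEFAULT_HALF_WIDTH

    def __post_init__(self) -> None:
        if "maf" in self.df.columns and np.any(self.df["maf"].to_numpy(float) <= 0):
            raise InputError("region maf must be positive")

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class ColocResult:
    """Posterior probabilities of H0-H4 for one region."""

    region: str
    nsnps: int
    pp: np.ndarray            # PP0..PP4
    priors: Tuple[float, float, float]
    snp_h4: pd.DataFrame      # per-SNP contribution to the H4 sum
    status: str = "ok"
    note: str = ""

    @property
    def pp4(self) -> float:
        return float(self.pp[4])


def extract_region(exposure: SummaryStats, outcome: SummaryStats, lead: str,
                   half_width: int = DEFAULT_HALF_WIDTH,
                   maf_min: float = DEFAULT_MAF_MIN) -> Optional[Tuple[Region, Region]]:
    """Intersected, harmonized exposure/outcome windows around a lead SNP.

    All SNPs within ``half_width`` of the lead present in both studies
    with MAF above ``maf_min`` in both; returns None (with the caller
    expected to log the reason) when fewer than 2 shared SNPs survive.
    """
    exp_df = exposure.df
    if lead not in set(exp_df["snp"]):
        raise InputError(f"lead SNP {lead} absent from exposure")
    lead_row = exp_df[exp_df["snp"] == lead].iloc[0]
    win_exp = exp_df[(exp_df["chr"] == lead_row["chr"])
                     & (abs(exp_df["pos"] - lead_row["pos"]) <= half_width)]
    try:
        hset = harmonize(SummaryStats(exposure.trait, win_exp), outcome)
    except Exception:
        return None
    df = hset.df
    maf = np.minimum(df["eaf"].to_numpy(float), 1 - df["eaf"].to_numpy(float))
    df = df.loc[maf > maf_min]
    if len(df) < 2:
        return None
    mk = lambda beta, se: pd.DataFrame({
        "snp": df["snp"].to_numpy(), "pos": df["pos"].to_numpy(),
        "beta": df[beta].to_numpy(float), "se": df[se].to_numpy(float),
        "maf": np.minimum(df["eaf"].to_numpy(float), 1 - df["eaf"].to_numpy(float)),
    })
    return (Region(lead, exposure.trait, mk("beta_exp", "se_exp"), half_width),
            Region(lead, outcome.trait, mk("beta_out", "se_out"), half_width))


def log_abf(beta, se, prior_sd: float = DEFAULT_PRIOR_SD):
    """Wakefield log approximate Bayes factor for one association.

    With shrinkage r = prior_sd^2/(prior_sd^2 + se^2) and z = beta/se:
    log ABF = 0.5 * (log(1 - r) + r z^2).  Zero in the no-information
    limit (se -> infinity), positive for large |z|.
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if np.any(se <= 0) or prior_sd <= 0:
        raise InputError("se and prior_sd must be positive")
    r = prior_sd**2 / (prior_sd**2 + se**2)
    z = beta / se
    return 0.5 * (np.log1p(-r) + r * z**2)


def coloc_abf(region_exp: Region, region_out: Region,
              p1: float = DEFAULT_P1, p2: float = DEFAULT_P2, p12: float = DEFAULT_P12,
              prior_sd_exp: float = DEFAULT_PRIOR_SD,
              prior_sd_out: float = DEFAULT_PRIOR_SD) -> ColocResult:
    """Posterior probabilities PP0-PP4 for one region pair.

    All sums run in log space: a 50-SNP region with |z| = 8 signals
    overflows the linear scale.  Single-SNP regions have PP3 = 0 (no
    two-distinct-variant configuration exists), and p12 = 0 forces
    PP4 = 0 exactly.
    """
    if list(region_exp.df["snp"]) != list(region_out.df["snp"]):
        raise InputError("regions must share an identical ordered SNP set")
    n = len(region_exp)
    if n < 1:
        raise InputError("empty region")
    if min(p1, p2, p12) < 0:
        raise InputError("priors must be non-negative")
    if p12 > min(p1, p2):
        import logging
        logging.getLogger(__name__).warning("p12 exceeds min(p1, p2)")
    la = log_abf(region_exp.df["beta"], region_exp.df["se"], prior_sd_exp)
    lb = log_abf(region_out.df["beta"], region_out.df["se"], prior_sd_out)

    lsum_a = logsumexp(la)
    lsum_b = logsumexp(lb)
    lsum_ab = logsumexp(la + lb)
    # H3: sum over i != j of ABF_a,i * ABF_b,j = sum_i sum_j - sum_i (i==j)
    both = lsum_a + lsum_b
    if n == 1:
        l3 = -np.inf
    else:
        diff = np.exp(lsum_ab - both)
        l3 = both + np.log1p(-min(diff, 1.0)) if diff < 1.0 else -np.inf

    lp1 = np.log(p1) if p1 > 0 else -np.inf
    lp2 = np.log(p2) if p2 > 0 else -np.inf
    lp12 = np.log(p12) if p12 > 0 else -np.inf
    lh = np.array([
        0.0,                    # H0: nothing
        lp1 + lsum_a,           # H1: exposure-only causal variant
        lp2 + lsum_b,           # H2: outcome-only causal variant
        lp1 + lp2 + l3,         # H3: two distinct causal variants
        lp12 + lsum_ab,         # H4: one shared causal variant
    ])
    pp = np.exp(lh - logsumexp(lh))
    pp = pp / pp.sum()
    with np.errstate(invalid="ignore"):
        h4_contrib = np.exp((la + lb) - lsum_ab)
    snp_h4 = pd.DataFrame({"snp": region_exp.df["snp"].to_numpy(), "h4_contribution": h4_contrib})
    return ColocResult(region_exp.lead, n, pp, (p1, p2, p12), snp_h4)


def verdict(results: List[ColocResult], h4_threshold: float = H4_THRESHOLD) -> Dict[str, object]:
    """Metabolite-level call: colocalized iff any region's PP4 exceeds the threshold."""
    computable = [r for r in results if r.status == "ok"]
    if not computable:
        return {"colocalized": False, "max_pp4": np.nan, "n_regions": 0,
                "note": "no computable regions"}
    max_pp4 = max(r.pp4 for r in computable)
    return {"colocalized": bool(max_pp4 > h4_threshold), "max_pp4": max_pp4,
            "n_regions": len(computable), "note": ""}
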