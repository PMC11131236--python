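"""Causal-effect estimators for two-sample MR.

All estimators consume a :class:`~metabomr.summary_io.HarmonizedSet` of
per-SNP exposure effects bx (SD of metabolite per allele) and outcome
effects by (years per allele), and return the causal effect of a 1 SD
increase in the metabolite on the outcome in years.

* Wald ratio: by/bx for a single instrument, first-order delta SE.
* IVW: inverse-variance-weighted meta-analysis of per-SNP ratios,
  equivalently weighted regression of by on bx through the origin with
  weights 1/se_by^2.  The default multiplicative random-effects model
  scales the fixed-effect SE by sqrt(Q/(k-1)) floored at 1, so it is
  never narrower than the fixed-effect model.
* MR-Egger: the same regression with a free intercept; a nonzero
  intercept estimates directional pleiotropy under InSIDE.
* Weighted median / weighted mode: pleiotropy-robust estimators over
  the per-SNP ratio distribution, with seeded parametric-bootstrap SEs.
* Multivariable IVW: joint regression of by on several exposures'
  effects (here a metabolite and BMI), giving conditional direct
  effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InputError
from .summary_io import HarmonizedSet

Z95 = stats.norm.ppf(0.975)


@dataclass
class MRResult:
    """One estimator's verdict for one (metabolite, outcome) pair."""

    exposure: str
    outcome: str
    method: str
    estimate: float = np.nan
    se: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p: float = np.nan
    nsnp: int = 0
    intercept: Optional[float] = None
    intercept_se: Optional[float] = None
    intercept_p: Optional[float] = None
    q: Optional[float] = None
    q_df: Optional[int] = None
    q_p: Optional[float] = None
    fdr_q: Optional[float] = None
    status: str = "ok"
    note: str = ""

    @classmethod
    def not_computable(cls, exposure: str, outcome: str, method: str, reason: str,
                       nsnp: int = 0) -> "MRResult":
        """Explicit marker mirroring a blank cell in a results table."""
        return cls(exposure, outcome, method, nsnp=nsnp, status="not_computable", note=reason)

    def __post_init__(self) -> None:
        if self.status == "ok" and np.isfinite(self.estimate) and np.isfinite(self.se):
            self.ci_low = self.estimate - Z95 * self.se
            self.ci_high = self.estimate + Z95 * self.se


def _two_sided_p(z: float) -> float:
    return float(np.clip(2.0 * stats.norm.sf(abs(z)), np.nextafter(0, 1), 1.0))


def wald_ratio(bx: float, bx_se: float, by: float, by_se: float,
               exposure: str = "", outcome: str = "") -> MRResult:
    """Single-instrument causal estimate by/bx with first-order delta SE."""
    if bx == 0:
        raise DegenerateInputError("Wald ratio undefined for bx = 0")
    est = by / bx
    se = by_se / abs(bx)
    return MRResult(exposure, outcome, "wald", est, se, p=_two_sided_p(est / se), nsnp=1)


def _ivw_core(bx: np.ndarray, by: np.ndarray, by_se: np.ndarray):
    w = 1.0 / by_se**2
    denom = float(np.sum(w * bx**2))
    est = float(np.sum(w * bx * by)) / denom
    se_fixed = float(np.sqrt(1.0 / denom))
    q = float(np.sum(w * (by - est * bx) ** 2))
    return est, se_fixed, q


def ivw(hset: HarmonizedSet, effects_model: str = "multiplicative_random") -> MRResult:
    """Inverse-variance-weighted meta-analysis of the per-SNP ratios.

    With a single instrument this reduces exactly to the Wald ratio
    (logged in the result note).
    """
    if effects_model not in ("fixed", "multiplicative_random"):
        raise InputError(f"unknown effects model {effects_model!r}")
    k = len(hset)
    if k < 1:
        return MRResult.not_computable(hset.metabolite, hset.outcome, "ivw", "no instruments")
    if k == 1:
        r = wald_ratio(hset.bx[0], hset.bx_se[0], hset.by[0], hset.by_se[0],
                       hset.metabolite, hset.outcome)
        r.method = "ivw"
        r.note = "single instrument: Wald ratio"
        r.__post_init__()
        return r
    est, se_fixed, q = _ivw_core(hset.bx, hset.by, hset.by_se)
    se = se_fixed
    if effects_model == "multiplicative_random":
        se = se_fixed * max(1.0, np.sqrt(q / (k - 1)))
    res = MRResult(hset.metabolite, hset.outcome, "ivw", est, se,
                   p=_two_sided_p(est / se), nsnp=k,
                   q=q, q_df=k - 1, q_p=float(stats.chi2.sf(q, k - 1)))
    return res


def egger(hset: HarmonizedSet) -> MRResult:
    """MR-Egger weighted regression with a free pleiotropy intercept.

    Instrument pairs are jointly flipped so every bx >= 0 before the
    fit; the residual scale is floored at 1 as in the IVW
    random-effects model and p-values use the normal reference.
    """
    k = len(hset)
    if k < 3:
        return MRResult.not_computable(hset.metabolite, hset.outcome, "egger",
                                       "needs >= 3 instruments", nsnp=k)
    sgn = np.where(hset.bx < 0, -1.0, 1.0)
    bx, by, by_se = sgn * hset.bx, sgn * hset.by, hset.by_se
    w = 1.0 / by_se**2
    X = np.column_stack([np.ones(k), bx])
    WX = X * w[:, None]
    xtx = X.T @ WX
    coef = np.linalg.solve(xtx, WX.T @ by)
    resid = by - X @ coef
    q = float(np.sum(w * resid**2))
    cov = np.linalg.inv(xtx)
    scale = max(1.0, np.sqrt(q / (k - 2)))
    se_i, se_s = np.sqrt(np.diag(cov)) * scale
    slope, inter = float(coef[1]), float(coef[0])
    # normal reference, as for ivw: the floored multiplicative scale already
    # guards against under-dispersion, and a t reference on top of it makes
    # the intercept test conservative
    p_slope = _two_sided_p(slope / se_s)
    p_inter = _two_sided_p(inter / se_i)
    return MRResult(hset.metabolite, hset.outcome, "egger", slope, float(se_s),
                    p=p_slope, nsnp=k, intercept=inter, intercept_se=float(se_i),
                    intercept_p=p_inter, q=q, q_df=k - 2,
                    q_p=float(stats.chi2.sf(q, k - 2)))


def _ratios(hset: HarmonizedSet):
    bx, by = hset.bx, hset.by
    ratio = by / bx
    # first-order variance of the ratio
    ratio_se = np.abs(hset.by_se / bx)
    return ratio, ratio_se


def _weighted_median(ratio: np.ndarray, weight: np.ndarray) -> float:
    order = np.argsort(ratio)
    b, w = ratio[order], weight[order]
    w = w / w.sum()
    cum = np.cumsum(w) - w / 2.0
    if cum[0] >= 0.5:
        return float(b[0])
    if cum[-1] <= 0.5:
        return float(b[-1])
    j = int(np.searchsorted(cum, 0.5))
    return float(b[j - 1] + (b[j] - b[j - 1]) * (0.5 - cum[j - 1]) / (cum[j] - cum[j - 1]))


def weighted_median(hset: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted median of per-SNP ratios; consistent if >= 50% of weight is valid.

    The estimate interpolates the inverse-variance-weighted percentile
    function at 0.5; the SE comes from a seeded parametric bootstrap
    redrawing bx and by from their sampling distributions.
    """
    k = len(hset)
    if k < 3:
        return MRResult.not_computable(hset.metabolite, hset.outcome, "weighted_median",
                                       "needs >= 3 instruments", nsnp=k)
    ratio, ratio_se = _ratios(hset)
    weight = 1.0 / ratio_se**2
    est = _weighted_median(ratio, weight)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = hset.bx + hset.bx_se * rng.standard_normal(k)
        by_b = hset.by + hset.by_se * rng.standard_normal(k)
        bx_b[bx_b == 0] = 1e-12
        r_b = by_b / bx_b
        w_b = bx_b**2 / hset.by_se**2
        boots[b] = _weighted_median(r_b, w_b)
    se = float(np.std(boots, ddof=1))
    p = _two_sided_p(est / se) if se > 0 else 1.0
    return MRResult(hset.metabolite, hset.outcome, "weighted_median", float(est), se,
                    p=p, nsnp=k)


def _silverman_bandwidth(x: np.ndarray) -> float:
    s = np.std(x, ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(s, iqr / 1.349) if iqr > 0 else s
    return 0.9 * spread * len(x) ** (-0.2)


def _weighted_mode(ratio: np.ndarray, weight: np.ndarray, bandwidth_factor: float) -> float:
    h = bandwidth_factor * _silverman_bandwidth(ratio)
    if not np.isfinite(h) or h <= 0:
        # degenerate spread: the heaviest value is the mode
        return float(ratio[np.argmax(weight)])
    lo, hi = ratio.min() - 3 * h, ratio.max() + 3 * h
    grid = np.linspace(lo, hi, 512)
    dens = (weight[:, None] * np.exp(-0.5 * ((grid[None, :] - ratio[:, None]) / h) ** 2)).sum(0)
    return float(grid[np.argmax(dens)])


def weighted_mode(hset: HarmonizedSet, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Mode of the weighted ratio density; consistent if the largest
    homogeneous cluster of instruments is valid (zero modal pleiotropy).

    Gaussian kernel density over per-SNP ratios, weights 1/ratio_se^2,
    bandwidth from a modified Silverman rule scaled by
    ``bandwidth_factor``; SE by seeded parametric bootstrap.
    """
    k = len(hset)
    if k < 3:
        return MRResult.not_computable(hset.metabolite, hset.outcome, "weighted_mode",
                                       "needs >= 3 instruments", nsnp=k)
    ratio, ratio_se = _ratios(hset)
    weight = 1.0 / ratio_se**2
    weight = weight / weight.sum()
    est = _weighted_mode(ratio, weight, bandwidth_factor)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = hset.bx + hset.bx_se * rng.standard_normal(k)
        by_b = hset.by + hset.by_se * rng.standard_normal(k)
        bx_b[bx_b == 0] = 1e-12
        r_b = by_b / bx_b
        w_b = bx_b**2 / hset.by_se**2
        boots[b] = _weighted_mode(r_b, w_b / w_b.sum(), bandwidth_factor)
    se = float(np.std(boots, ddof=1))
    p = _two_sided_p(est / se) if se > 0 else 1.0
    return MRResult(hset.metabolite, hset.outcome, "weighted_mode", float(est), se,
                    p=p, nsnp=k)


@dataclass
class MVMRResult:
    """Conditional (direct) effects of several exposures on one outcome."""

    exposures: List[str]
    outcome: str
    estimates: np.ndarray = field(default_factory=lambda: np.array([]))
    ses: np.ndarray = field(default_factory=lambda: np.array([]))
    ps: np.ndarray = field(default_factory=lambda: np.array([]))
    nsnp: int = 0
    status: str = "ok"
    note: str = ""

    def as_results(self) -> List[MRResult]:
        out = []
        for i, name in enumerate(self.exposures):
            if self.status != "ok":
                out.append(MRResult.not_computable(name, self.outcome, "mvmr", self.note,
                                                   nsnp=self.nsnp))
            else:
                out.append(MRResult(name, self.outcome, "mvmr", float(self.estimates[i]),
                                    float(self.ses[i]), p=float(self.ps[i]), nsnp=self.nsnp))
        return out


def mvmr_ivw(bx_matrix: np.ndarray, by: np.ndarray, by_se: np.ndarray,
             exposures: Sequence[str], outcome: str = "") -> MVMRResult:
    """Multivariable IVW: weighted regression of by on all exposures' effects.

    ``bx_matrix`` is (n_snps, n_exposures) over the union instrument
    set; requires more instruments than exposures.  SEs use the
    multiplicative residual scale floored at 1.
    """
    bx_matrix = np.atleast_2d(np.asarray(bx_matrix, float))
    n, p = bx_matrix.shape
    if n <= p:
        return MVMRResult(list(exposures), outcome, nsnp=n, status="not_computable",
                          note=f"needs more instruments ({n}) than exposures ({p})")
    w = 1.0 / np.asarray(by_se, float) ** 2
    WX = bx_matrix * w[:, None]
    xtx = bx_matrix.T @ WX
    # pinv keeps degenerate exposures (e.g. an all-zero column) from
    # poisoning the others; their own coefficient collapses to 0
    xtx_inv = np.linalg.pinv(xtx)
    coef = xtx_inv @ (WX.T @ by)
    resid = by - bx_matrix @ coef
    q = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(q / (n - p))) if n > p else 1.0
    with np.errstate(invalid="ignore"):
        ses = np.sqrt(np.diag(xtx_inv)) * scale
    with np.errstate(invalid="ignore", divide="ignore"):
        ps = 2 * stats.norm.sf(np.abs(coef / ses))
    return MVMRResult(list(exposures), outcome, coef, ses, ps, nsnp=n)


def fdr_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values over one testing family."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(list(pvalues), float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
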