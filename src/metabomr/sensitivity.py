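"""Heterogeneity, pleiotropy-outlier and directionality diagnostics.

Instruments that affect the outcome through paths other than the
exposure (horizontal pleiotropy) bias MR estimates.  This module
quantifies that risk three ways:

* Cochran's Q over per-SNP ratios (chi-square with k-1 df under
  homogeneity; Rucker's Q' on the Egger residuals with k-2 df),
* MR-PRESSO: a parametric simulation of the leave-one-out residual sum
  of squares that yields a global pleiotropy p-value and per-SNP
  outlier p-values with Bonferroni flagging, plus the outlier-corrected
  IVW re-estimate,
* Steiger directionality: each instrument should explain more variance
  in the exposure than in the outcome; the per-SNP comparison uses
  r^2 = 2 beta^2 f (1-f) on standardized effects (or t^2/(t^2+n-2)
  when allele frequency is unavailable) and a Fisher-z two-sample test.

``reverse_mr`` runs the full estimator battery with exposure and
outcome roles swapped, testing whether the outcome causally shifts the
metabolite instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .estimators import MRResult, _ivw_core, egger, ivw, weighted_median, weighted_mode
from .instruments import build_instruments
from .summary_io import HarmonizedSet, SummaryStats, harmonize_with_proxies
from .synthetic import LDPanel


def cochran_q(hset: HarmonizedSet, fit: MRResult) -> Tuple[float, int, float]:
    """Heterogeneity Q of the per-SNP ratios around a fitted model.

    For an IVW fit, Q = sum w_j (ratio_j - theta)^2 with first-order
    ratio weights w_j = bx_j^2/se_by_j^2 and k-1 df; for an Egger fit,
    the residual Q' around intercept + slope*bx with k-2 df.
    """
    k = len(hset)
    need = 3 if fit.method == "egger" else 2
    if k < need or fit.status != "ok":
        raise InputError(f"Cochran Q needs >= {need} instruments and a computable fit")
    w = 1.0 / hset.by_se**2
    if fit.method == "egger":
        sgn = np.where(hset.bx < 0, -1.0, 1.0)
        pred = fit.intercept + fit.estimate * (sgn * hset.bx)
        q = float(np.sum(w * (sgn * hset.by - pred) ** 2))
        df = k - 2
    else:
        q = float(np.sum(w * (hset.by - fit.estimate * hset.bx) ** 2))
        df = k - 1
    return q, df, float(stats.chi2.sf(q, df))


@dataclass
class PressoResult:
    """MR-PRESSO global test, outlier flags, and corrected estimate."""

    global_rss: float
    global_p: float
    outlier_indices: List[int]
    outlier_p: np.ndarray
    corrected: Optional[MRResult]
    status: str = "ok"
    note: str = ""


def _loo_ivw(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates, vectorized over SNPs (and sims if 2-D)."""
    num = np.sum(w * bx * by, axis=-1, keepdims=True) - w * bx * by
    den = np.sum(w * bx**2, axis=-1, keepdims=True) - w * bx**2
    return num / den


def presso(hset: HarmonizedSet, n_sim: int = 1000, seed: int = 0,
           alpha_outlier: float = 0.05) -> PressoResult:
    """Pleiotropy RESidual Sum and Outlier test.

    The observed weighted residual sum of squares around leave-one-out
    IVW predictions is ranked within ``n_sim`` parametric simulations
    in which exposure and outcome effects are redrawn from their
    sampling distributions under the leave-one-out fit; the rank tail
    probability (with the +1 correction, so the attainable minimum is
    1/(n_sim+1)) is the global pleiotropy p.  Per-SNP residual terms
    are ranked the same way and flagged at alpha/k (Bonferroni); the
    corrected result re-runs IVW without flagged SNPs.
    """
    k = len(hset)
    if k < 4:
        return PressoResult(np.nan, np.nan, [], np.array([]), None,
                            status="not_computable", note="needs >= 4 instruments")
    # canonical SNP order so results do not depend on row order
    order = np.argsort(hset.df["snp"].to_numpy())
    bx_all, by_all = hset.bx[order], hset.by[order]
    bx_se_all, by_se_all = hset.bx_se[order], hset.by_se[order]

    def _pass(idx: np.ndarray, pass_rng: np.random.Generator):
        bx, by = bx_all[idx], by_all[idx]
        bx_se, by_se = bx_se_all[idx], by_se_all[idx]
        kk = idx.size
        w = 1.0 / by_se**2
        theta_loo = _loo_ivw(bx, by, w)
        obs_terms = w * (by - theta_loo * bx) ** 2
        bx_sim = bx + bx_se * pass_rng.standard_normal((n_sim, kk))
        by_sim = theta_loo * bx + by_se * pass_rng.standard_normal((n_sim, kk))
        theta_sim = _loo_ivw(bx_sim, by_sim, np.broadcast_to(w, (n_sim, kk)))
        sim_terms = w * (by_sim - theta_sim * bx_sim) ** 2
        sim_rss = sim_terms.sum(axis=1)
        obs_rss = float(obs_terms.sum())
        global_p = float((np.sum(sim_rss >= obs_rss) + 1) / (n_sim + 1))
        out_p = (np.sum(sim_terms >= obs_terms, axis=0) + 1) / (n_sim + 1)
        return obs_rss, global_p, obs_terms, out_p

    # iterative outlier removal: one worst Bonferroni-significant SNP per
    # pass, so a gross outlier cannot drag honest instruments down with it
    # through the contaminated leave-one-out fits
    seeds = np.random.SeedSequence(seed).spawn(k)
    active = np.arange(k)
    flagged_sorted: List[int] = []
    first = None
    for step in range(k):
        if active.size < 4:
            break
        res = _pass(active, np.random.default_rng(seeds[step]))
        if first is None:
            first = res
        _, _, obs_terms, out_p = res
        sig = np.nonzero(out_p < alpha_outlier / active.size)[0]
        if sig.size == 0:
            break
        worst = sig[np.argmax(obs_terms[sig])]
        flagged_sorted.append(int(active[worst]))
        active = np.delete(active, worst)

    obs_rss, global_p, _, out_p_first = first
    outlier_p = np.empty(k)
    outlier_p[order] = out_p_first           # first-pass per-SNP p, caller order
    flagged = sorted(int(order[i]) for i in flagged_sorted)

    corrected = None
    if flagged and k - len(flagged) >= 2:
        keep = np.setdiff1d(np.arange(k), flagged)
        sub = HarmonizedSet(hset.metabolite, hset.outcome,
                            hset.df.iloc[keep].reset_index(drop=True))
        corrected = ivw(sub)
        corrected.note = f"PRESSO outlier-corrected (removed {len(flagged)})"
    return PressoResult(obs_rss, global_p, flagged, np.asarray(outlier_p), corrected)


def _fisher_z_p(r_exp: np.ndarray, r_out: np.ndarray, n_exp: float, n_out: float) -> np.ndarray:
    z = (np.arctanh(np.clip(r_exp, 0, 1 - 1e-12))
         - np.arctanh(np.clip(r_out, 0, 1 - 1e-12)))
    se = np.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    return 2.0 * stats.norm.sf(np.abs(z) / se)


def steiger_filter(hset: HarmonizedSet, n_exp: Optional[float] = None,
                   n_out: Optional[float] = None, method: str = "eaf") -> pd.DataFrame:
    """Per-SNP directionality check: does the SNP explain more exposure variance?

    Returns a frame with r2_exp, r2_out, ``direction`` (True when
    r2_exp > r2_out) and the Fisher-z comparison p; the aggregate study
    verdict is ``direction.all()``.  ``method='eaf'`` uses
    2 beta^2 f (1-f) on standardized effects; ``method='t'`` (and the
    fallback when eaf is missing) uses r^2 = t^2/(t^2 + n - 2).
    """
    if method not in ("eaf", "t"):
        raise InputError(f"unknown Steiger method {method!r}")
    df = hset.df
    n_exp = n_exp if n_exp is not None else float(np.nanmedian(df.get("n_exp", np.nan)))
    n_out = n_out if n_out is not None else float(np.nanmedian(df.get("n_out", np.nan)))
    if not (np.isfinite(n_exp) and np.isfinite(n_out)):
        raise InputError("Steiger needs sample sizes for both studies")

    eaf = df["eaf"].to_numpy(float)
    het = 2.0 * eaf * (1.0 - eaf)

    def _r2(beta, se, n):
        t2 = (beta / se) ** 2
        r2_t = t2 / (t2 + n - 2.0)
        if method == "t":
            return r2_t
        r2_f = het * beta**2
        return np.where(np.isfinite(r2_f), r2_f, r2_t)

    r2_exp = _r2(hset.bx, hset.bx_se, n_exp)
    r2_out = _r2(hset.by, hset.by_se, n_out)
    p = _fisher_z_p(np.sqrt(np.clip(r2_exp, 0, 1)), np.sqrt(np.clip(r2_out, 0, 1)),
                    n_exp, n_out)
    p = np.where(r2_exp == r2_out, 1.0, p)
    return pd.DataFrame({
        "snp": df["snp"], "r2_exp": r2_exp, "r2_out": r2_out,
        "direction": r2_exp > r2_out, "p": p,
    })


def reverse_mr(outcome_as_exposure: SummaryStats, metabolite_as_outcome: SummaryStats,
               panel: LDPanel, p_threshold: float = 5e-8,
               n_boot: int = 500, seed: int = 0) -> Dict[str, MRResult]:
    """Bidirectional check: instrument the outcome, estimate its effect on the metabolite.

    Instruments are selected from the outcome GWAS at the genome-wide
    threshold and clumped on the panel; IVW, Egger, weighted median and
    weighted mode are returned (the last three as not-computable
    markers when fewer than three reverse instruments survive).
    """
    label = outcome_as_exposure.trait
    iv = build_instruments(outcome_as_exposure, panel, p_threshold=p_threshold)
    if iv is None:
        nc = {m: MRResult.not_computable(label, metabolite_as_outcome.trait, m,
                                         "no genome-wide-significant reverse instruments")
              for m in ("ivw", "egger", "weighted_median", "weighted_mode")}
        return nc
    exp_sub = outcome_as_exposure.subset(iv.snps())
    hset = harmonize_with_proxies(exp_sub, metabolite_as_outcome, panel)
    return {
        "ivw": ivw(hset),
        "egger": egger(hset),
        "weighted_median": weighted_median(hset, n_boot=n_boot, seed=seed),
        "weighted_mode": weighted_mode(hset, n_boot=n_boot, seed=seed + 1),
    }
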