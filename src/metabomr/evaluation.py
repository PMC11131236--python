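"""Seeded study-level benchmark experiments.

Self-contained experiments that exercise the whole stack and return the
quantities a reviewer would check: estimator/oracle agreement, bias and
CI coverage under a known causal effect, test sizes under the null,
outlier detection, colocalization behaviour on constructed regions,
enrichment exactness against brute-force enumeration, and the
end-to-end study funnel.  Each function takes a seed and is
deterministic given it.
"""

from __future__ import annotations

from typing import Dict

import numpy as np
import pandas as pd

from .coloc import Region, coloc_abf
from .enrichment import MetaboliteSetDB, hypergeom_ora
from .estimators import egger, ivw, mvmr_ivw, wald_ratio
from .instruments import f_statistic, variance_explained
from .sensitivity import cochran_q, presso
from .summary_io import HarmonizedSet
from .synthetic import SimTruth, simulate_gwas_pair, simulate_ld_panel
from .pipeline import StudyConfig, run_pipeline
from .synthetic import simulate_study


def _hset(bx, bx_se, by, by_se):
    k = len(bx)
    return HarmonizedSet("m", "o", pd.DataFrame({
        "snp": [f"rs{i:04d}" for i in range(k)], "ea": "A", "oa": "G", "eaf": 0.3,
        "beta_exp": bx, "se_exp": np.broadcast_to(bx_se, (k,)),
        "beta_out": by, "se_out": np.broadcast_to(by_se, (k,)),
        "n_exp": 25_000.0, "n_out": 200_000.0,
    }))


def _join(exposure, outcome):
    merged = exposure.df.merge(outcome.df, on="snp", suffixes=("_exp", "_out"))
    return _hset(merged["beta_exp"].to_numpy(), merged["se_exp"].to_numpy(),
                 merged["beta_out"].to_numpy(), merged["se_out"].to_numpy())


def ivw_oracle_discrepancy(n_sets: int = 1000, seed: int = 0) -> Dict[str, float]:
    """IVW vs the closed-form weighted-ratio mean, and vs Wald at one SNP."""
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for _ in range(n_sets):
        k = int(rng.integers(2, 20))
        bx = rng.uniform(0.05, 0.5, k) * rng.choice([-1.0, 1.0], k)
        by = rng.normal(0, 0.1, k)
        by_se = rng.uniform(0.01, 0.2, k)
        w = bx**2 / by_se**2
        oracle = float(np.sum(w * (by / bx)) / np.sum(w))
        est = ivw(_hset(bx, 0.01, by, by_se)).estimate
        max_diff = max(max_diff, abs(est - oracle))
    one = ivw(_hset([0.2], 0.01, [0.07], 0.03))
    wald = wald_ratio(0.2, 0.01, 0.07, 0.03)
    single_diff = max(abs(one.estimate - wald.estimate), abs(one.se - wald.se))
    return {"max_abs_diff": max_diff, "single_snp_diff": single_diff}


def ivw_recovery(n_reps: int = 500, theta: float = 0.2, k: int = 10,
                 seed: int = 0) -> Dict[str, float]:
    """Bias and nominal-95% CI coverage of IVW under a known causal effect.

    Exposure effects are drawn strong (global F far above 30) so
    weak-instrument attenuation is negligible at these sample sizes.
    """
    rng = np.random.default_rng(seed)
    panel = simulate_ld_panel(k, 1, 0.0, seed=seed)
    estimates, covered = [], []
    for _ in range(n_reps):
        b = rng.uniform(0.2, 0.4, k)
        truth = SimTruth(theta, b, np.zeros(k), 100_000, 300_000,
                         seed=int(rng.integers(2**31)))
        exp, out = simulate_gwas_pair(panel, truth, swap_fraction=0, flip_fraction=0)
        res = ivw(_join(exp, out))
        estimates.append(res.estimate)
        covered.append(res.ci_low <= theta <= res.ci_high)
    return {"mean_bias": float(np.mean(estimates) - theta),
            "coverage": float(np.mean(covered))}


def mvmr_recovery(n_reps: int = 500, theta_m: float = 0.2, theta_b: float = 0.1,
                  k: int = 12, seed: int = 0) -> Dict[str, float]:
    """Conditional-effect recovery for a metabolite + BMI exposure pair."""
    rng = np.random.default_rng(seed)
    bias_m, bias_b, cov_m, cov_b = [], [], [], []
    for _ in range(n_reps):
        bx_m = rng.uniform(0.1, 0.5, k) + rng.normal(0, 0.003, k)
        bx_b = rng.uniform(0.1, 0.5, k) + rng.normal(0, 0.003, k)
        by_se = np.full(k, 0.02)
        by = theta_m * bx_m + theta_b * bx_b + by_se * rng.standard_normal(k)
        res = mvmr_ivw(np.column_stack([bx_m, bx_b]), by, by_se, ["m", "bmi"])
        bias_m.append(res.estimates[0] - theta_m)
        bias_b.append(res.estimates[1] - theta_b)
        cov_m.append(abs(res.estimates[0] - theta_m) <= 1.96 * res.ses[0])
        cov_b.append(abs(res.estimates[1] - theta_b) <= 1.96 * res.ses[1])
    return {"mean_bias_metabolite": float(np.mean(bias_m)),
            "mean_bias_bmi": float(np.mean(bias_b)),
            "coverage_metabolite": float(np.mean(cov_m)),
            "coverage_bmi": float(np.mean(cov_b))}


def null_calibration(n_reps: int = 500, seed: int = 0,
                     presso_n_sim: int = 1000) -> Dict[str, float]:
    """Test sizes at alpha = 0.05 under theta = 0 with no pleiotropy.

    IVW and the PRESSO global test run on 10-instrument sets; the Egger
    intercept and Cochran Q, whose residual-scale floor bites hardest
    at small k, on 20-instrument sets.
    """
    rng = np.random.default_rng(seed)
    rej = {"ivw": 0, "egger_intercept": 0, "cochran_q": 0, "presso_global": 0}

    def _null_hset(panel, k):
        b = rng.uniform(0.1, 0.5, k)
        truth = SimTruth(0.0, b, np.zeros(k), 100_000, 300_000,
                         seed=int(rng.integers(2**31)))
        exp, out = simulate_gwas_pair(panel, truth, swap_fraction=0, flip_fraction=0)
        return _join(exp, out)

    panel10 = simulate_ld_panel(10, 1, 0.0, seed=seed)
    panel20 = simulate_ld_panel(20, 1, 0.0, seed=seed + 1)
    for _ in range(n_reps):
        h10 = _null_hset(panel10, 10)
        fit = ivw(h10)
        rej["ivw"] += fit.p < 0.05
        pr = presso(h10, n_sim=presso_n_sim, seed=int(rng.integers(2**31)))
        rej["presso_global"] += pr.global_p < 0.05
        h20 = _null_hset(panel20, 20)
        rej["egger_intercept"] += egger(h20).intercept_p < 0.05
        _, _, qp = cochran_q(h20, ivw(h20))
        rej["cochran_q"] += qp < 0.05
    return {name: count / n_reps for name, count in rej.items()}


def presso_outlier_experiment(seed: int = 11, theta: float = 0.2,
                              k: int = 11) -> Dict[str, float]:
    """One gross pleiotropic SNP among concordant instruments."""
    rng = np.random.default_rng(seed)
    bx = rng.uniform(0.1, 0.4, k)
    by = theta * bx + rng.normal(0, 0.01, k)
    inj = k // 2
    by[inj] += 10 * theta * bx[inj]            # direct effect 10x the causal path
    hset = _hset(bx, 0.003, by, 0.01)
    res = presso(hset, n_sim=1000, seed=seed)
    before = ivw(hset)
    after = res.corrected if res.corrected is not None else before
    return {
        "global_p": res.global_p,
        "injected_flagged": float(inj in res.outlier_indices),
        "estimate_before": before.estimate,
        "estimate_after": after.estimate,
        "moved_toward_truth": float(abs(after.estimate - theta)
                                    < abs(before.estimate - theta)),
    }


def coloc_experiments(seed: int = 0, n_snps: int = 50) -> Dict[str, float]:
    """Posterior normalization, prior-proportional limit, shared/distinct signals."""
    rng = np.random.default_rng(seed)

    def region(z, trait):
        return Region("lead", trait, pd.DataFrame({
            "snp": [f"rs{i:03d}" for i in range(len(z))],
            "pos": 1000 * (np.arange(len(z)) + 1),
            "beta": np.asarray(z) * 0.02, "se": 0.02, "maf": 0.3,
        }))

    # flat-evidence single-SNP region (se >> prior_sd, so every ABF = 1):
    # posteriors must be exactly prior-proportional
    flat_expected_pp4 = 1e-5 / (1 + 2e-4 + 1e-5)
    big = Region("lead", "a", pd.DataFrame({
        "snp": ["rs0"], "pos": [1000], "beta": [0.0], "se": [1e9], "maf": [0.3]}))
    flat = coloc_abf(big, big)

    sum_err = 0.0
    for _ in range(50):
        za = rng.normal(0, 2, n_snps)
        zb = rng.normal(0, 2, n_snps)
        res = coloc_abf(region(za, "a"), region(zb, "b"))
        sum_err = max(sum_err, abs(res.pp.sum() - 1.0))

    shared = np.zeros(n_snps)
    shared[n_snps // 2] = 8.0
    noise_a = rng.normal(0, 1, n_snps) * (shared == 0)
    noise_b = rng.normal(0, 1, n_snps) * (shared == 0)
    res_shared = coloc_abf(region(shared + noise_a, "a"), region(shared + noise_b, "b"))

    za, zb = np.zeros(n_snps), np.zeros(n_snps)
    za[5], zb[n_snps - 5] = 8.0, 8.0
    res_distinct = coloc_abf(region(za + rng.normal(0, 1, n_snps) * (za == 0), "a"),
                             region(zb + rng.normal(0, 1, n_snps) * (zb == 0), "b"))
    return {
        "pp_sum_max_err": sum_err,
        "flat_pp4": float(flat.pp4),
        "flat_pp4_expected": flat_expected_pp4,
        "flat_pp4_err": float(abs(flat.pp4 - flat_expected_pp4)),
        "shared_pp4": float(res_shared.pp4),
        "distinct_pp3": float(res_distinct.pp[3]),
        "distinct_pp4": float(res_distinct.pp4),
    }


def formula_checks() -> Dict[str, float]:
    """The variance-explained and F-statistic arithmetic on reference inputs."""
    return {
        "variance_explained": float(variance_explained(0.5, 0.5)),
        "f_statistic": float(f_statistic(0.01, 1001, 1)),
    }


def ora_exactness(max_n: int = 15) -> Dict[str, float]:
    """Hypergeometric tail vs bitmask brute-force enumeration, all N <= max_n."""
    max_err = 0.0
    checked = 0
    for N in range(2, max_n + 1):
        universe = [f"m{i}" for i in range(N)]
        # tally #subsets of each (size n, overlap j) by popcount enumeration
        for K in range(0, N + 1):
            kmask = (1 << K) - 1
            counts = np.zeros((N + 1, K + 1), dtype=np.int64)
            for mask in range(1 << N):
                n = bin(mask).count("1")
                j = bin(mask & kmask).count("1")
                counts[n, j] += 1
            db = MetaboliteSetDB({"s": universe[:K]}) if K else MetaboliteSetDB({"s": []})
            for n in range(1, N + 1):
                total = counts[n].sum()
                for k_obs in range(0, min(K, n) + 1):
                    brute = counts[n, k_obs:].sum() / total
                    selection = universe[:k_obs] + universe[K:K + (n - k_obs)]
                    if len(selection) != n:
                        continue
                    res = hypergeom_ora(selection, db, universe)
                    max_err = max(max_err, abs(res["p"].iloc[0] - brute))
                    checked += 1
    return {"max_abs_err": max_err, "n_checked": float(checked)}


def funnel_experiment(n_seeds: int = 100, n_metabolites: int = 50, n_causal: int = 5,
                      seed: int = 0) -> Dict[str, float]:
    """End-to-end study: causal-metabolite containment and count conservation."""
    rng = np.random.default_rng(seed)
    contained, conserved = [], []
    fp_rates = []
    for _ in range(n_seeds):
        s = int(rng.integers(2**31))
        data = simulate_study(n_metabolites=n_metabolites, n_causal=n_causal, seed=s)
        bundle = run_pipeline(StudyConfig(seed=s), data)
        pri = set(bundle.manifest["prioritized"])
        contained.append(set(data.causal) <= pri)
        c = bundle.manifest["counts"]
        conserved.append(
            c["mr_tested"] == c["prioritized"] + c["non_prioritized"]
            and c["coloc_tested"] == c["colocalized"] + c["non_colocalized"]
            + c["coloc_skipped"])
        fp_rates.append(len(pri - set(data.causal)) / (n_metabolites - n_causal))
    return {
        "containment_rate": float(np.mean(contained)),
        "counts_conserved_rate": float(np.mean(conserved)),
        "false_prioritization_rate": float(np.mean(fp_rates)),
    }
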