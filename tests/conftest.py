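import numpy as np
import pandas as pd
import pytest

from metabomr import HarmonizedSet, SimTruth, simulate_gwas_pair, simulate_ld_panel


def make_hset(bx, bx_se, by, by_se, metabolite="metab", outcome="outcome"):
    """HarmonizedSet straight from effect arrays (panel-free unit testing)."""
    bx = np.asarray(bx, float)
    k = bx.size
    df = pd.DataFrame({
        "snp": [f"rs{i:04d}" for i in range(k)],
        "ea": "A", "oa": "G", "eaf": 0.3,
        "beta_exp": bx, "se_exp": np.broadcast_to(np.asarray(bx_se, float), (k,)),
        "beta_out": np.asarray(by, float),
        "se_out": np.broadcast_to(np.asarray(by_se, float), (k,)),
        "n_exp": 25_000.0, "n_out": 200_000.0,
    })
    return HarmonizedSet(metabolite, outcome, df)


@pytest.fixture
def small_panel():
    """Three AR(1) blocks of five SNPs, rho = 0.9, > 500 kb apart."""
    return simulate_ld_panel(3, 5, 0.9, seed=42)


@pytest.fixture
def strong_pair(small_panel):
    """Exposure/outcome GWAS pair with one strong causal SNP per block, theta = 0.2."""
    m = len(small_panel)
    b = np.zeros(m)
    b[[2, 7, 12]] = 0.3
    truth = SimTruth(0.2, b, np.zeros(m), 100_000, 300_000, seed=7)
    return simulate_gwas_pair(small_panel, truth, swap_fraction=0.0, flip_fraction=0.0)


def join_pair(exposure, outcome, snps=None):
    """Panel-oriented exposure/outcome join into a HarmonizedSet (no corruption)."""
    merged = exposure.df.merge(outcome.df, on="snp", suffixes=("_exp", "_out"))
    if snps is not None:
        merged = merged[merged["snp"].isin(set(snps))]
    df = pd.DataFrame({
        "snp": merged["snp"], "ea": merged["ea_exp"], "oa": merged["oa_exp"],
        "eaf": merged["eaf_exp"],
        "beta_exp": merged["beta_exp"], "se_exp": merged["se_exp"],
        "p_exp": merged["p_exp"], "n_exp": merged["n_exp"],
        "beta_out": merged["beta_out"], "se_out": merged["se_out"],
        "p_out": merged["p_out"], "n_out": merged["n_out"],
    })
    return HarmonizedSet(exposure.trait, outcome.trait, df)
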