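"""Colocalization: Wakefield ABFs, five-hypothesis posteriors, verdicts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabomr import SimTruth, coloc_abf, extract_region, log_abf, simulate_gwas_pair, simulate_ld_panel, verdict
from metabomr.coloc import ColocResult, Region
from metabomr.errors import InputError


def _region(betas, ses, trait="t", lead=None, maf=0.3):
    k = len(betas)
    df = pd.DataFrame({
        "snp": [f"rs{i:03d}" for i in range(k)], "pos": 1000 * (np.arange(k) + 1),
        "beta": np.asarray(betas, float), "se": np.asarray(ses, float), "maf": maf,
    })
    return Region(lead or "rs000", trait, df)


class TestLogABF:
    def test_closed_form_value(self):
        # r = 0.5, z = 0 -> 0.5 * ln(0.5)
        assert log_abf(0.0, 0.15, prior_sd=0.15) == pytest.approx(0.5 * np.log(0.5))

    def test_no_information_limit(self):
        assert log_abf(0.0, 1e8, prior_sd=0.15) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_z_squared(self):
        vals = [log_abf(z * 0.02, 0.02) for z in (0, 2, 4, 8)]
        assert np.all(np.diff(vals) > 0)
        assert vals[-1] > 0

    def test_invalid_se_rejected(self):
        with pytest.raises(InputError):
            log_abf(0.1, 0.0)


class TestColocABF:
    def test_flat_single_snp_posteriors_prior_proportional(self):
        a = _region([0.0], [1e8])
        b = _region([0.0], [1e8])
        res = coloc_abf(a, b, p1=1e-4, p2=1e-4, p12=1e-5)
        norm = 1 + 2e-4 + 1e-5
        assert res.pp[0] == pytest.approx(1 / norm, abs=1e-9)
        assert res.pp[4] == pytest.approx(1e-5 / norm, abs=1e-9)
        assert res.pp[3] == 0.0  # no two-distinct-variant configuration

    def test_shared_signal_colocalizes(self):
        rng = np.random.default_rng(31)
        z = np.zeros(50)
        z[25] = 8.0
        noise = rng.normal(0, 1, 50) * (np.arange(50) != 25)
        a = _region((z + noise) * 0.02, [0.02] * 50)
        b = _region((z + rng.normal(0, 1, 50) * (np.arange(50) != 25)) * 0.02, [0.02] * 50)
        res = coloc_abf(a, b)
        assert res.pp4 > 0.8

    def test_distinct_signals_favor_h3(self):
        rng = np.random.default_rng(32)
        za, zb = np.zeros(50), np.zeros(50)
        za[10], zb[40] = 8.0, 8.0
        a = _region((za + rng.normal(0, 1, 50) * (za == 0)) * 0.02, [0.02] * 50)
        b = _region((zb + rng.normal(0, 1, 50) * (zb == 0)) * 0.02, [0.02] * 50)
        res = coloc_abf(a, b)
        assert res.pp[3] > res.pp[4]

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 40))
    def test_posteriors_sum_to_one(self, seed, k):
        rng = np.random.default_rng(seed)
        a = _region(rng.normal(0, 0.1, k), rng.uniform(0.01, 0.1, k))
        b = _region(rng.normal(0, 0.1, k), rng.uniform(0.01, 0.1, k))
        res = coloc_abf(a, b)
        assert res.pp.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(res.pp >= 0)

    def test_zero_p12_kills_h4(self):
        rng = np.random.default_rng(33)
        a = _region(rng.normal(0, 0.1, 10), [0.02] * 10)
        b = _region(rng.normal(0, 0.1, 10), [0.02] * 10)
        assert coloc_abf(a, b, p12=0.0).pp[4] == 0.0

    def test_pp4_monotone_in_p12(self):
        rng = np.random.default_rng(34)
        z = np.zeros(20)
        z[10] = 6.0
        a = _region(z * 0.02 + rng.normal(0, 0.002, 20), [0.02] * 20)
        b = _region(z * 0.02 + rng.normal(0, 0.002, 20), [0.02] * 20)
        pp4s = [coloc_abf(a, b, p12=p12).pp4 for p12 in (1e-8, 1e-6, 1e-5, 1e-4)]
        assert np.all(np.diff(pp4s) >= 0)

    def test_snp_set_mismatch_rejected(self):
        a = _region([0.1, 0.2], [0.02, 0.02])
        b = _region([0.1, 0.2, 0.3], [0.02] * 3)
        with pytest.raises(InputError):
            coloc_abf(a, b)


class TestExtractRegion:
    @pytest.fixture
    def pair(self):
        panel = simulate_ld_panel(2, 6, 0.9, seed=5, maf_range=(0.05, 0.45),
                                  palindromic_fraction=0.0)
        m = len(panel)
        b = np.zeros(m)
        b[2] = 0.4
        truth = SimTruth(0.3, b, np.zeros(m), 50_000, 200_000, seed=6)
        return panel, *simulate_gwas_pair(panel, truth, swap_fraction=0, flip_fraction=0)

    def test_window_restricts_to_block(self, pair):
        panel, exp, out = pair
        lead = panel.snps["snp"].iloc[2]
        regions = extract_region(exp, out, lead, half_width=500_000)
        assert regions is not None
        rexp, rout = regions
        assert list(rexp.df["snp"]) == list(panel.snps["snp"][:6])
        assert list(rexp.df["snp"]) == list(rout.df["snp"])

    def test_low_maf_snps_excluded(self, pair):
        panel, exp, out = pair
        exp.df.loc[exp.df.index[1], "eaf"] = 0.005
        out.df.loc[out.df.index[1], "eaf"] = 0.005
        lead = panel.snps["snp"].iloc[2]
        rexp, _ = extract_region(exp, out, lead, maf_min=0.01)
        assert panel.snps["snp"].iloc[1] not in set(rexp.df["snp"])

    def test_exposure_only_snps_dropped_by_intersection(self, pair):
        panel, exp, out = pair
        missing = panel.snps["snp"].iloc[3]
        from metabomr.summary_io import SummaryStats
        out2 = SummaryStats(out.trait, out.df[out.df["snp"] != missing])
        lead = panel.snps["snp"].iloc[2]
        rexp, _ = extract_region(exp, out2, lead)
        assert missing not in set(rexp.df["snp"])

    def test_absent_lead_rejected(self, pair):
        _, exp, out = pair
        with pytest.raises(InputError):
            extract_region(exp, out, "rs_not_here")


class TestVerdict:
    def _res(self, pp4):
        pp = np.array([0.0, 0.0, 0.0, 1 - pp4, pp4])
        return ColocResult("rs1", 10, pp, (1e-4, 1e-4, 1e-5), pd.DataFrame())

    def test_any_region_rule(self):
        v = verdict([self._res(0.4), self._res(0.85)])
        assert v["colocalized"] and v["max_pp4"] == pytest.approx(0.85)

    def test_strictly_greater_than_threshold(self):
        assert not verdict([self._res(0.79)], h4_threshold=0.79)["colocalized"]

    def test_no_regions_is_negative_with_reason(self):
        v = verdict([])
        assert not v["colocalized"] and v["note"]


def test_region_coloc_recovers_shared_causal_snp(small_panel):
    """End-to-end through the generator: one shared causal SNP per block."""
    m = len(small_panel)
    b = np.zeros(m)
    b[2] = 0.4
    truth = SimTruth(0.3, b, np.zeros(m), 100_000, 300_000, seed=9)
    exp, out = simulate_gwas_pair(small_panel, truth, swap_fraction=0, flip_fraction=0)
    lead = small_panel.snps["snp"].iloc[2]
    rexp, rout = extract_region(exp, out, lead)
    res = coloc_abf(rexp, rout)
    assert res.pp4 > 0.8
    top = res.snp_h4.sort_values("h4_contribution").iloc[-1]["snp"]
    assert top == lead
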