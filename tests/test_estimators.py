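"""MR estimators: Wald, IVW, Egger, weighted median/mode, MVMR, FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabomr import (
    egger,
    fdr_adjust,
    ivw,
    mvmr_ivw,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from metabomr.errors import DegenerateInputError, InputError
from metabomr.estimators import _weighted_median, _weighted_mode

from conftest import make_hset


class TestWaldRatio:
    def test_ratio_and_delta_se(self):
        r = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert r.estimate == pytest.approx(0.5)
        assert r.se == pytest.approx(0.2)

    def test_zero_outcome_effect(self):
        assert wald_ratio(0.1, 0.01, 0.0, 0.02).estimate == 0.0

    def test_negative_exposure_effect(self):
        r = wald_ratio(-0.1, 0.01, 0.05, 0.02)
        assert r.estimate == pytest.approx(-0.5)
        assert r.se == pytest.approx(0.2)

    def test_degenerate_instrument(self):
        with pytest.raises(DegenerateInputError):
            wald_ratio(0.0, 0.01, 0.05, 0.02)


class TestIVW:
    def test_closed_form_two_snp_example(self):
        h = make_hset([0.2, 0.4], 0.01, [0.1, 0.1], 0.1)
        assert ivw(h).estimate == pytest.approx(0.3)  # (0.02+0.04)/(0.04+0.16)

    def test_homogeneous_ratios_random_equals_fixed(self):
        h = make_hset([0.1, 0.2], 0.01, [0.05, 0.10], 0.1)
        fixed = ivw(h, effects_model="fixed")
        rand = ivw(h, effects_model="multiplicative_random")
        assert rand.q == pytest.approx(0.0, abs=1e-20)
        assert rand.se == pytest.approx(fixed.se)

    def test_single_snp_reduces_to_wald(self):
        h = make_hset([0.2], 0.01, [0.1], 0.05)
        res = ivw(h)
        wald = wald_ratio(0.2, 0.01, 0.1, 0.05)
        assert res.estimate == wald.estimate and res.se == wald.se

    def test_unknown_effects_model_rejected(self):
        h = make_hset([0.2, 0.4], 0.01, [0.1, 0.1], 0.1)
        with pytest.raises(InputError):
            ivw(h, effects_model="additive")

    def test_equals_weighted_mean_of_ratios(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            k = rng.integers(2, 15)
            bx = rng.uniform(0.05, 0.5, k) * rng.choice([-1, 1], k)
            by = rng.normal(0, 0.1, k)
            by_se = rng.uniform(0.01, 0.2, k)
            h = make_hset(bx, 0.01, by, by_se)
            w = bx**2 / by_se**2
            oracle = np.sum(w * (by / bx)) / np.sum(w)
            assert ivw(h).estimate == pytest.approx(oracle, abs=1e-12)


class TestEgger:
    def test_exact_line_with_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_hset(bx, 0.01, 0.1 + 0.5 * bx, 0.05)
        res = egger(h)
        assert res.intercept == pytest.approx(0.1, abs=1e-12)
        assert res.estimate == pytest.approx(0.5, abs=1e-12)
        assert res.q == pytest.approx(0.0, abs=1e-18)

    def test_line_through_origin(self):
        bx = np.array([0.1, 0.2, 0.3])
        res = egger(make_hset(bx, 0.01, 0.5 * bx, 0.05))
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.estimate == pytest.approx(0.5, abs=1e-12)

    def test_too_few_instruments_marked(self):
        res = egger(make_hset([0.1, 0.2], 0.01, [0.05, 0.1], 0.05))
        assert res.status == "not_computable"

    def test_intercept_null_rarely_rejected_without_pleiotropy(self):
        """No directional pleiotropy: intercept test keeps its size."""
        rng = np.random.default_rng(42)
        clean = 0
        for _ in range(500):
            bx = rng.uniform(0.1, 0.5, 20)
            by = 0.2 * bx + rng.normal(0, 0.02, 20)
            res = egger(make_hset(bx, 0.005, by, 0.02))
            clean += res.intercept_p > 0.05
        assert clean / 500 >= 0.90


class TestWeightedMedian:
    def test_plain_median_equal_weights(self):
        assert _weighted_median(np.array([1.0, 2.0, 3.0]), np.ones(3)) == pytest.approx(2.0)

    def test_outlier_robustness(self):
        assert _weighted_median(np.array([1.0, 2.0, 100.0]), np.ones(3)) == pytest.approx(2.0)

    def test_interpolation_rule_hand_computed(self):
        # cumulative standardized weights 0.375, 0.875 -> crossing at 1.25
        est = _weighted_median(np.array([1.0, 2.0]), np.array([0.75, 0.25]))
        assert est == pytest.approx(1.25)

    def test_estimator_on_harmonized_set(self):
        bx = np.array([0.2, 0.25, 0.3, 0.35])
        h = make_hset(bx, 0.005, 0.4 * bx, 0.02)
        res = weighted_median(h, n_boot=200, seed=1)
        assert res.estimate == pytest.approx(0.4, abs=0.01)
        assert res.se > 0

    def test_bootstrap_seeded(self):
        bx = np.array([0.2, 0.25, 0.3, 0.35])
        h = make_hset(bx, 0.005, 0.4 * bx + [0, 0.01, -0.01, 0.02], 0.02)
        a = weighted_median(h, n_boot=100, seed=9)
        b = weighted_median(h, n_boot=100, seed=9)
        assert a.se == b.se


class TestWeightedMode:
    def test_degenerate_identical_ratios(self):
        h = make_hset(np.full(5, 0.2), 0.005, np.full(5, 0.08), 0.02)
        assert weighted_mode(h, n_boot=50, seed=0).estimate == pytest.approx(0.4, abs=1e-6)

    def test_majority_cluster_wins(self):
        ratios = np.array([0.4, 0.4, 0.4, 5.0])
        bx = np.full(4, 0.2)
        h = make_hset(bx, 0.005, ratios * bx, 0.02)
        res = weighted_mode(h, bandwidth_factor=0.5, n_boot=50, seed=0)
        assert res.estimate == pytest.approx(0.4, abs=0.05)

    def test_heavier_cluster_beats_larger_spread(self):
        # two clusters; the one at 0.2 carries far more weight
        bx = np.array([0.5, 0.5, 0.5, 0.1, 0.1])
        ratios = np.array([0.2, 0.21, 0.19, 0.8, 0.82])
        h = make_hset(bx, 0.005, ratios * bx, 0.02)
        res = weighted_mode(h, bandwidth_factor=0.5, n_boot=50, seed=0)
        # grid oracle over the same weighted density
        ratio_se = 0.02 / bx
        w = 1 / ratio_se**2
        est = _weighted_mode(ratios, w / w.sum(), 0.5)
        assert res.estimate == pytest.approx(est)
        assert abs(res.estimate - 0.2) < 0.05

    def test_too_few_instruments_marked(self):
        res = weighted_mode(make_hset([0.1, 0.2], 0.01, [0.05, 0.1], 0.05))
        assert res.status == "not_computable"


class TestMVMR:
    def test_exact_linear_system(self):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.1, 0.5, (6, 2))
        by = 0.3 * bx[:, 0] + 0.1 * bx[:, 1]
        res = mvmr_ivw(bx, by, np.full(6, 0.02), ["metab", "bmi"])
        assert res.estimates == pytest.approx([0.3, 0.1], abs=1e-10)

    def test_zero_bmi_column_reduces_to_univariable(self):
        rng = np.random.default_rng(4)
        bx = rng.uniform(0.1, 0.5, 8)
        by = 0.3 * bx + rng.normal(0, 0.02, 8)
        by_se = np.full(8, 0.02)
        multi = mvmr_ivw(np.column_stack([bx, np.zeros(8)]), by, by_se, ["m", "bmi"])
        uni = ivw(make_hset(bx, 0.005, by, by_se), effects_model="fixed")
        assert multi.estimates[0] == pytest.approx(uni.estimate, abs=1e-12)

    def test_underdetermined_marked(self):
        res = mvmr_ivw(np.ones((2, 2)), np.ones(2), np.ones(2), ["a", "b"])
        assert res.status == "not_computable"

    def test_mediated_effect_conditionally_null(self):
        """Metabolite acting only through BMI has zero direct effect."""
        rng = np.random.default_rng(5)
        hits = []
        for _ in range(100):
            bx_m = rng.uniform(0.1, 0.5, 12)
            bx_b = 0.5 * bx_m + rng.normal(0, 0.02, 12)  # BMI downstream of metabolite
            by = 0.4 * bx_b + rng.normal(0, 0.02, 12)    # outcome only via BMI
            res = mvmr_ivw(np.column_stack([bx_m, bx_b]), by, np.full(12, 0.02),
                           ["m", "bmi"])
            hits.append(abs(res.estimates[0]) < 3 * res.ses[0])
        assert np.mean(hits) > 0.9


class TestFDR:
    def test_hand_computed_bh(self):
        assert fdr_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.37]) == pytest.approx([0.37])

    def test_identical_ps_unchanged(self):
        assert fdr_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_invalid_p_rejected(self):
        with pytest.raises(InputError):
            fdr_adjust([0.0, 0.5])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=30))
    def test_q_monotone_in_p(self, ps):
        order = np.argsort(ps)
        qs = fdr_adjust(ps)
        assert np.all(np.diff(qs[order]) >= -1e-12)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_joint_sign_flip_leaves_estimators_invariant(seed):
    rng = np.random.default_rng(seed)
    k = 6
    bx = rng.uniform(0.1, 0.5, k)
    by = 0.3 * bx + rng.normal(0, 0.02, k)
    flip = rng.random(k) < 0.5
    sgn = np.where(flip, -1.0, 1.0)
    h1 = make_hset(bx, 0.01, by, 0.02)
    h2 = make_hset(sgn * bx, 0.01, sgn * by, 0.02)
    assert ivw(h1).estimate == pytest.approx(ivw(h2).estimate, abs=1e-12)
    assert egger(h1).estimate == pytest.approx(egger(h2).estimate, abs=1e-10)
    a = weighted_median(h1, n_boot=10, seed=0).estimate
    b = weighted_median(h2, n_boot=10, seed=0).estimate
    assert a == pytest.approx(b, abs=1e-10)


def test_egger_resists_balanced_pleiotropy_better_than_ivw():
    """Under InSIDE with directional pleiotropy, Egger's slope bias is smaller."""
    rng = np.random.default_rng(8)
    ivw_bias, egger_bias = [], []
    for _ in range(200):
        bx = rng.uniform(0.1, 0.5, 25)
        alpha = rng.normal(0.02, 0.01, 25)          # directional, independent of bx
        by = 0.2 * bx + alpha + rng.normal(0, 0.005, 25)
        h = make_hset(bx, 0.002, by, 0.005)
        ivw_bias.append(ivw(h).estimate - 0.2)
        egger_bias.append(egger(h).estimate - 0.2)
    assert abs(np.mean(egger_bias)) < abs(np.mean(ivw_bias))
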