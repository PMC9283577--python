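"""Wald ratio, IVW, MR-Egger and weighted-median estimators."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone
from _oracles import wls_slope_through_origin, wls_with_intercept

from tsmr.estimators import (
    CollinearityError,
    EggerEstimator,
    InsufficientInstrumentsError,
    IVWEstimator,
    WeightedMedianEstimator,
    egger,
    ivw_mre,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
    weighted_median_point,
)
from conftest import make_instruments


class TestWaldRatio:
    def test_null_outcome_effect(self):
        est = wald_ratio(make_instruments([0.1], [0.0], [0.01])[0])
        assert est.theta == 0.0 and est.pval == 1.0

    def test_direct_arithmetic(self):
        est = wald_ratio(make_instruments([0.1], [0.05], [0.01])[0])
        assert est.theta == pytest.approx(0.5) and est.se == pytest.approx(0.1)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            wald_ratio(make_instruments([0.0], [0.05], [0.01])[0])


class TestIVW:
    def test_identical_ratios_give_zero_q_and_unit_scale(self):
        est, het = ivw_mre(make_instruments([1, 2], [0.5, 1.0], [0.1, 0.1]))
        assert est.theta == pytest.approx(0.5)
        assert het.Q == pytest.approx(0.0, abs=1e-12)
        assert est.scale_factor == 1.0

    def test_weighted_least_squares_through_origin(self):
        est, _ = ivw_mre(
            make_instruments([0.1, 0.2, 0.3], [0.05, 0.04, 0.12], [0.01, 0.02, 0.03])
        )
        assert est.theta == pytest.approx(11 / 30, rel=1e-12)

    def test_hand_computed_q(self):
        est, het = ivw_mre(make_instruments([1, 1], [0.4, 0.6], [0.1, 0.1]))
        assert est.theta == pytest.approx(0.5)
        assert het.Q == pytest.approx(2.0, rel=1e-12)
        assert est.scale_factor == pytest.approx(math.sqrt(2.0))

    def test_equals_weighted_mean_of_wald_ratios(self, rng):
        bx = rng.normal(0.1, 0.03, 15)
        by = rng.normal(0.05, 0.03, 15)
        so = rng.uniform(0.01, 0.05, 15)
        est, _ = ivw_mre(make_instruments(bx, by, so))
        w = bx**2 / so**2
        assert est.theta == pytest.approx(np.sum(w * by / bx) / np.sum(w), abs=1e-10)

    def test_matches_wls_oracle(self, rng):
        bx = rng.normal(0.1, 0.05, 10)
        by = rng.normal(0.0, 0.05, 10)
        so = rng.uniform(0.01, 0.1, 10)
        model = IVWEstimator().fit(bx, by, se_out=so)
        assert model.theta_ == pytest.approx(wls_slope_through_origin(bx, by, so), abs=1e-10)

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw_mre(make_instruments([0.1], [0.05], [0.01]))

    def test_sklearn_protocol(self):
        model = IVWEstimator(random_effects=False)
        assert clone(model).get_params() == {"random_effects": False}
        fitted = model.fit([0.1, 0.2], [0.05, 0.1], se_out=[0.01, 0.01])
        np.testing.assert_allclose(fitted.predict([1.0, 2.0]), [0.5, 1.0])


class TestEgger:
    def test_perfect_line_recovered(self):
        # beta_out = 0.1 + 0.5 * beta_exp, equal SEs
        bx = [1.0, 2.0, 3.0]
        by = [0.1 + 0.5 * x for x in bx]
        slope, intercept, het = egger(make_instruments(bx, by, [0.1] * 3))
        assert intercept.theta == pytest.approx(0.1, rel=1e-10)
        assert slope.theta == pytest.approx(0.5, rel=1e-10)
        assert het.Q == pytest.approx(0.0, abs=1e-10)

    def test_matches_wls_oracle_with_negative_exposure_effects(self, rng):
        bx = rng.normal(0.0, 0.2, 12)  # mixed signs exercise the orientation
        by = rng.normal(0.0, 0.1, 12)
        so = rng.uniform(0.02, 0.08, 12)
        model = EggerEstimator().fit(bx, by, se_out=so)
        b0, b1 = wls_with_intercept(bx, by, so)
        assert model.intercept_ == pytest.approx(b0, abs=1e-8)
        assert model.theta_ == pytest.approx(b1, abs=1e-8)

    def test_zero_intercept_mode_reproduces_ivw(self, rng):
        bx = rng.normal(0.1, 0.1, 8)
        by = rng.normal(0.05, 0.05, 8)
        so = rng.uniform(0.01, 0.05, 8)
        constrained = EggerEstimator(fit_intercept=False).fit(bx, by, se_out=so)
        ivw = IVWEstimator().fit(bx, by, se_out=so)
        assert constrained.theta_ == pytest.approx(ivw.theta_, abs=1e-10)

    def test_collinear_design_rejected(self):
        with pytest.raises(CollinearityError):
            egger(make_instruments([0.2, 0.2, -0.2], [0.1, 0.2, 0.1], [0.1] * 3))

    def test_insufficient_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(make_instruments([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))


class TestWeightedMedian:
    def test_unweighted_median_of_three(self):
        assert weighted_median_point(np.array([0.2, 0.5, 0.9]), np.ones(3)) == 0.5

    def test_interpolation_with_four_equal_weights(self):
        est = weighted_median_point(np.array([0.1, 0.2, 0.6, 0.7]), np.ones(4))
        assert est == pytest.approx(0.4, rel=1e-12)

    def test_dominant_weight_limit(self):
        # as one variant's weight approaches 1 the estimate approaches its ratio
        ratios = np.array([0.3, 2.0, 2.0, 2.0])
        eps = 1e-7
        weights = np.array([1 - eps, eps / 3, eps / 3, eps / 3])
        assert abs(weighted_median_point(ratios, weights) - 0.3) < 1e-6

    def test_estimate_with_bootstrap_se(self):
        insts = make_instruments([0.1, 0.1, 0.1], [0.02, 0.05, 0.09],
                                 [0.01, 0.01, 0.01])
        est = weighted_median(insts, n_boot=500, seed=42)
        assert est.theta == pytest.approx(0.5)
        assert est.se > 0 and est.ci_low <= est.theta <= est.ci_high

    def test_seed_is_mandatory(self):
        insts = make_instruments([0.1] * 3, [0.05] * 3, [0.01] * 3)
        with pytest.raises(ValueError, match="random_state"):
            WeightedMedianEstimator().fit(insts)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_bounded_by_extreme_ratios_and_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        J = int(rng.integers(3, 12))
        ratios = np.sort(rng.normal(0, 1, J))
        if len(np.unique(ratios)) < J:
            return
        weights = rng.uniform(0.1, 1, J)
        est = weighted_median_point(ratios, weights)
        assert ratios.min() - 1e-12 <= est <= ratios.max() + 1e-12
        perm = rng.permutation(J)
        assert weighted_median_point(ratios[perm], weights[perm]) == pytest.approx(
            est, abs=1e-12
        )


class TestSignEquivariance:
    def test_negating_outcome_negates_all_estimators(self, rng):
        bx = rng.normal(0.12, 0.03, 10)
        by = rng.normal(0.06, 0.04, 10)
        so = rng.uniform(0.01, 0.05, 10)
        pos = make_instruments(bx, by, so)
        neg = make_instruments(bx, -by, so)

        assert wald_ratio(neg[0]).theta == pytest.approx(-wald_ratio(pos[0]).theta)
        assert ivw_mre(neg)[0].theta == pytest.approx(-ivw_mre(pos)[0].theta, abs=1e-12)
        assert egger(neg)[0].theta == pytest.approx(-egger(pos)[0].theta, abs=1e-12)
        wm_pos = weighted_median(pos, n_boot=200, seed=1)
        wm_neg = weighted_median(neg, n_boot=200, seed=1)
        assert wm_neg.theta == pytest.approx(-wm_pos.theta, abs=1e-12)

        or_pos = to_odds_ratio(ivw_mre(pos)[0])
        or_neg = to_odds_ratio(ivw_mre(neg)[0])
        assert or_neg.or_point == pytest.approx(1.0 / or_pos.or_point, rel=1e-10)


class TestOddsRatioConversion:
    def test_null_effect_maps_to_unit_or(self):
        est, _ = ivw_mre(make_instruments([1, 2], [0.0, 0.0], [0.1, 0.1]))
        assert to_odds_ratio(est).or_point == pytest.approx(1.0)

    def test_monotone_transform_of_ci(self):
        insts = make_instruments([1.0, 1.0, 1.0],
                                 [math.log(2)] * 3, [0.05, 0.05, 0.05])
        est, _ = ivw_mre(insts)
        orr = to_odds_ratio(est)
        assert orr.or_point == pytest.approx(2.0, rel=1e-10)
        assert orr.or_low == pytest.approx(math.exp(est.ci_low), rel=1e-12)
        assert orr.or_high == pytest.approx(math.exp(est.ci_high), rel=1e-12)

    def test_order_preserved(self, rng):
        bx = rng.normal(0.1, 0.02, 6)
        by = rng.normal(-0.05, 0.03, 6)
        est, _ = ivw_mre(make_instruments(bx, by, rng.uniform(0.01, 0.03, 6)))
        orr = to_odds_ratio(est)
        assert orr.or_low <= orr.or_point <= orr.or_high
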