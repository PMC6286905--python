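"""Planning decisions: thresholds, zones, recommendations, legacy rule."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prrtplan import (
    Action,
    LinearModelFit,
    RiskPolicy,
    classify_zones,
    exceedance_probability,
    first_cycle_threshold,
    legacy_expected_cumulative,
    legacy_withhold,
    perturb_for_observer_variability,
    recommend,
    threshold_sensitivity,
    worst_case_variability,
)
from prrtplan.decision import ACTION_CAUTION


class TestFirstCycleThreshold:
    def test_noiseless_closed_form(self, noiseless_fits):
        # step-function predictive law: T1 = (25 - a) / (1 + b)
        t1 = first_cycle_threshold(noiseless_fits["simple"])
        assert t1 == pytest.approx((25 - 2.0) / (1 + 3.0), abs=1e-3)

    def test_bisection_lands_just_below_risk_level(self, fitted_models):
        policy = RiskPolicy()
        t1 = first_cycle_threshold(fitted_models["simple"], policy)
        risk = exceedance_probability(
            fitted_models["simple"], [t1], known_cumulative=t1, threshold=25.0
        ).probability_exceed
        assert policy.continue_risk - 0.002 <= risk < policy.continue_risk

    def test_higher_threshold_raises_t1(self, fitted_models):
        t25 = first_cycle_threshold(fitted_models["simple"], RiskPolicy(dose_threshold=25))
        t29 = first_cycle_threshold(
            fitted_models["simple"], RiskPolicy(dose_threshold=29), bracket=(1e-3, 29.0)
        )
        assert t29 > t25

    def test_negative_slope_rejected(self):
        fit = LinearModelFit.from_coefficients(("D1",), [30.0, -1.0], residual_scale=1.0)
        with pytest.raises(ValueError, match="monotone"):
            first_cycle_threshold(fit)

    def test_risk_never_attained_reported(self):
        # huge intercept: already above the risk level at the bracket edge
        fit = LinearModelFit.from_coefficients(("D1",), [40.0, 1.0], residual_scale=1.0)
        with pytest.raises(ValueError, match="never attained"):
            first_cycle_threshold(fit)


class TestClassifyZones:
    def test_zone_labels_follow_probabilities(self, fitted_models):
        policy = RiskPolicy()
        for d1 in (2.0, 5.0, 7.0, 9.0, 12.0):
            for d2 in (2.0, 5.0, 7.0, 9.0, 12.0):
                state = classify_zones(
                    fitted_models["joint34"], fitted_models["d3"], d1, d2, policy
                )
                p4 = state.probabilities["p_exceed_4_cycles"]
                p3 = state.probabilities["p_exceed_3_cycles"]
                assert state.four_cycle_zone == (
                    "A" if p4 < 0.10 else ("C" if p4 > 0.95 else "B")
                )
                assert state.three_cycle_zone == (
                    "D" if p3 < 0.10 else ("F" if p3 > 0.95 else "E")
                )

    def test_give_three_zone_pair(self, noiseless_fits):
        # (6.5, 6.5): four-cycle total 25.77 Gy > 25 but three-cycle 19.68 < 25
        state = classify_zones(noiseless_fits["joint34"], noiseless_fits["d3"], 6.5, 6.5)
        assert (state.four_cycle_zone, state.three_cycle_zone) == ("C", "D")

    def test_stop_zone_dominates(self, noiseless_fits):
        state = classify_zones(noiseless_fits["joint34"], noiseless_fits["d3"], 9.5, 9.5)
        assert state.three_cycle_zone == "F"

    def test_rejects_nonpositive_doses(self, noiseless_fits):
        with pytest.raises(ValueError):
            classify_zones(noiseless_fits["joint34"], noiseless_fits["d3"], 0.0, 5.0)


class TestRecommend:
    # hand-computed oracle under zero residual noise: the predictive law is
    # a step function, so every action reduces to threshold arithmetic with
    # T1 = (25 - 2)/(1 + 3) = 5.75 and the reference coefficients
    HAND_CASES = [
        ([5.0], Action.COMPLETE_ALL_FOUR_NO_PTS),
        ([5.74], Action.COMPLETE_ALL_FOUR_NO_PTS),
        ([5.8], Action.CONTINUE_WITH_PTS),
        ([9.0], Action.CONTINUE_WITH_PTS),
        ([5.9, 5.9], Action.COMPLETE_ALL_FOUR_NO_PTS),  # 4-cycle total 23.5 Gy
        ([3.0, 3.0], Action.COMPLETE_ALL_FOUR_NO_PTS),
        ([6.5, 6.5], Action.GIVE_THREE_ONLY_NO_PTS),  # 25.8 Gy after 4, 19.7 after 3
        ([8.0, 8.0], Action.GIVE_THREE_ONLY_NO_PTS),  # 31.4 after 4, 24.1 after 3
        ([9.5, 9.5], Action.STOP_NOW),  # 28.6 Gy already after 3 cycles
        ([4.0, 4.0, 4.0], Action.COMPLETE_ALL_FOUR_NO_PTS),  # 16.2 Gy with cycle 4
        ([9.0, 9.0, 9.0], Action.STOP_NOW),  # 35.3 Gy with cycle 4
    ]

    @pytest.mark.parametrize("doses,expected", HAND_CASES)
    def test_noiseless_hand_oracle(self, noiseless_fits, doses, expected):
        assert recommend(doses, noiseless_fits).action == expected

    def test_first_cycle_threshold_reported(self, fitted_models):
        state = recommend([1.0], fitted_models)
        assert "first_cycle_threshold" in state.probabilities

    def test_rejects_empty_and_complete(self, noiseless_fits):
        with pytest.raises(ValueError):
            recommend([], noiseless_fits)
        with pytest.raises(ValueError):
            recommend([5, 5, 5, 5], noiseless_fits)

    @settings(max_examples=300, deadline=None)
    @given(
        data=st.lists(st.floats(0.5, 11.5), min_size=1, max_size=3),
        which=st.integers(0, 2),
        bump=st.floats(0.05, 3.0),
    )
    def test_monotone_safety(self, fitted_models, data, which, bump):
        """Raising any observed dose never relaxes the recommendation."""
        which = which % len(data)
        bumped = list(data)
        bumped[which] += bump
        a = recommend(data, fitted_models).action
        b = recommend(bumped, fitted_models).action
        assert ACTION_CAUTION[b] >= ACTION_CAUTION[a]


class TestLegacyRule:
    def test_boundary_at_18_75_gy(self):
        assert legacy_expected_cumulative([6.25, 6.25, 6.25]) == 25.0

    def test_single_dose_doubles(self):
        assert legacy_expected_cumulative([10.0]) == 20.0

    def test_withhold_above_threshold(self):
        assert legacy_expected_cumulative([7.0, 7.0, 7.0]) == pytest.approx(28.0)
        assert legacy_withhold([7.0, 7.0, 7.0])
        assert not legacy_withhold([6.0, 6.0, 6.0])

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.integers(1, 40), min_size=1, max_size=4))
    def test_identity_cum_times_p_plus_1_over_p(self, doses):
        expected = Fraction(sum(doses)) * Fraction(len(doses) + 1, len(doses))
        assert legacy_expected_cumulative(doses) == pytest.approx(float(expected), rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            legacy_expected_cumulative([])


class TestObserverVariability:
    def test_worst_case_inter_observer(self):
        assert worst_case_variability(-6.5, 6.8) == pytest.approx(13.3)

    def test_shifted_threshold_dose_displays_6_3(self):
        shifted = perturb_for_observer_variability(5.6, 0.133)
        assert round(shifted, 1) == 6.3

    def test_zero_shift_is_identity(self):
        assert perturb_for_observer_variability(4.2, 0.0) == 4.2

    def test_shift_below_minus_one_rejected(self):
        with pytest.raises(ValueError):
            perturb_for_observer_variability(4.2, -1.0)


class TestThresholdSensitivity:
    def test_probability_decreases_with_threshold(self, fitted_models):
        table = threshold_sensitivity(fitted_models["joint34"], [6.2, 6.2], 12.4, [25.0, 29.0])
        p25, p29 = table["probability_exceed"]
        assert p29 < p25

    def test_half_at_exact_margin(self, fitted_models):
        fit = fitted_models["joint34"]
        from prrtplan import predict_new_observation

        point, _ = predict_new_observation(fit, [6.0, 6.0])
        table = threshold_sensitivity(fit, [6.0, 6.0], 12.0, [12.0 + point])
        assert table["probability_exceed"][0] == pytest.approx(0.5)

    def test_noiseless_probabilities_are_steps(self, noiseless_fits):
        table = threshold_sensitivity(
            noiseless_fits["joint34"], [6.0, 6.0], 12.0, [20.0, 23.89, 30.0]
        )
        assert list(table["probability_exceed"]) == [1.0, 0.5, 0.0]

    def test_unsorted_rejected(self, noiseless_fits):
        with pytest.raises(ValueError):
            threshold_sensitivity(noiseless_fits["joint34"], [6, 6], 12.0, [29.0, 25.0])


class TestRiskPolicy:
    def test_invalid_levels_rejected(self):
        with pytest.raises(ValueError):
            RiskPolicy(continue_risk=0.97, preclusion_risk=0.05)
        with pytest.raises(ValueError):
            RiskPolicy(dose_threshold=-5.0)
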