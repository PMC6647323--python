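"""Survival statistics and the confirmatory testing machinery.

Log-rank and Cox estimates are checked against a hand-computed risk-set
table, a brute-force partial-likelihood grid search, and lifelines as an
independent implementation.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import ndtri
from scipy.stats import norm

from aetrial import (
    CombinationWeights,
    Decision,
    StageData,
    closed_testing_decision,
    combination_pvalue,
    combination_statistic,
    estimate_hazard_ratio,
    hochberg_intersection_p,
    interim_decision,
    logrank_z,
    one_sided_logrank_p,
)

probs = st.floats(min_value=1e-6, max_value=1.0 - 1e-6)


@pytest.fixture
def six_patient_data():
    return StageData(
        time=np.array([1.0, 2.0, 2.5, 3.0, 4.0, 5.0]),
        event=np.array([1, 0, 1, 1, 1, 0], dtype=bool),
        arm=np.array([0, 1, 0, 1, 0, 1], dtype=bool),
    )


class TestLogrank:
    def test_hand_computed_risk_set_table(self):
        """Control events at t=1,2; experimental at t=3,4; all observed.

        Risk-set arithmetic gives O1=2, E1=3.1667, V=0.47222, hence
        Z = 1.16667/sqrt(0.47222) = 1.69775.
        """
        d = StageData([1, 2, 3, 4], [1, 1, 1, 1], [0, 0, 1, 1])
        assert logrank_z(d) == pytest.approx(1.1666667 / math.sqrt(0.4722222), abs=1e-6)
        assert one_sided_logrank_p(d) == pytest.approx(1 - norm.cdf(1.697749), abs=1e-6)

    def test_symmetric_data_gives_half(self):
        d = StageData([1, 1, 2, 2], [1, 1, 1, 1], [0, 1, 0, 1])
        assert one_sided_logrank_p(d) == pytest.approx(0.5)

    def test_arm_swap_flips_p(self, six_patient_data):
        d = six_patient_data
        swapped = StageData(d.time, d.event, ~d.arm)
        assert one_sided_logrank_p(swapped) == pytest.approx(
            1.0 - one_sided_logrank_p(d), abs=1e-12
        )

    def test_matches_lifelines_chi_square(self, six_patient_data):
        from lifelines.statistics import logrank_test

        d = six_patient_data
        res = logrank_test(d.time[d.arm], d.time[~d.arm], d.event[d.arm], d.event[~d.arm])
        assert logrank_z(d) ** 2 == pytest.approx(res.test_statistic, rel=1e-10)

    @pytest.mark.parametrize(
        "time, event, arm",
        [
            ([1, 2], [1, 1], [1, 1]),  # single arm
            ([1, 2], [0, 0], [0, 1]),  # zero events
        ],
    )
    def test_degenerate_data_is_an_error(self, time, event, arm):
        with pytest.raises(ValueError):
            one_sided_logrank_p(StageData(time, event, arm))


class TestCox:
    def test_identical_arms_give_unit_ratio(self):
        t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        e = np.ones(6, bool)
        g = np.array([0, 0, 0, 1, 1, 1], bool)
        # fully tied across arms at every event time: no arm information
        assert estimate_hazard_ratio(StageData(t, e, g)) == pytest.approx(1.0, abs=1e-8)

    def test_matches_grid_search_oracle(self, six_patient_data):
        """Brute-force maximisation of the partial likelihood to 1e-4."""
        d = six_patient_data

        def nll(beta):
            order = np.argsort(d.time)
            ll = 0.0
            for i in order:
                if d.event[i]:
                    risk = d.time >= d.time[i]
                    ll += beta * d.arm[i] - math.log(np.sum(np.exp(beta * d.arm[risk])))
            return -ll

        grid = np.linspace(-4.0, 4.0, 80001)
        beta_star = grid[int(np.argmin([nll(b) for b in grid]))]
        assert math.log(estimate_hazard_ratio(d)) == pytest.approx(beta_star, abs=1e-4)

    def test_matches_lifelines(self, six_patient_data):
        from lifelines import CoxPHFitter

        d = six_patient_data
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": d.time, "e": d.event.astype(int), "g": d.arm.astype(int)}),
            "t", "e",
        )
        assert math.log(estimate_hazard_ratio(d)) == pytest.approx(
            float(cph.params_.iloc[0]), abs=1e-3
        )

    def test_efron_ties_match_lifelines(self):
        from lifelines import CoxPHFitter

        t = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 3.0, 4.0, 4.0])
        e = np.array([1, 1, 0, 1, 1, 1, 1, 0], bool)
        g = np.array([1, 0, 1, 1, 0, 0, 1, 0], bool)
        d = StageData(t, e, g)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e.astype(int), "g": g.astype(int)}), "t", "e"
        )
        assert math.log(estimate_hazard_ratio(d)) == pytest.approx(
            float(cph.params_.iloc[0]), abs=1e-3
        )

    def test_consistency_at_large_n(self):
        rng = np.random.default_rng(8)
        n = 10**4
        g = rng.random(n) < 0.5
        lam = np.where(g, 0.5, 1.0)
        t = rng.exponential(1.0 / lam)
        est = estimate_hazard_ratio(StageData(t, np.ones(n, bool), g))
        assert est == pytest.approx(0.5, abs=0.02)

    def test_monotone_likelihood_capped_with_warning(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 1, 0, 0], bool)
        g = np.array([1, 1, 0, 0], bool)  # all events in the experimental arm
        with pytest.warns(RuntimeWarning, match="monotone"):
            est = estimate_hazard_ratio(StageData(t, e, g))
        assert est == pytest.approx(1e3)


class TestInterimDecision:
    @pytest.mark.parametrize(
        "hr_O, hr_P, expected",
        [
            (1.2, 1.1, Decision.FUTILITY),
            (0.9, 1.3, Decision.CONTINUE_O),  # continue O regardless of HR_P
            (1.05, 0.8, Decision.ENRICH_P),
            (1.0, 1.0, Decision.FUTILITY),  # threshold tie counts as not beneficial
            (1.0, 0.99, Decision.ENRICH_P),
        ],
    )
    def test_rules(self, hr_O, hr_P, expected):
        assert interim_decision(hr_O, hr_P, 1.0, 1.0) is expected

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            interim_decision(-1.0, 0.5, 1.0, 1.0)

    @given(st.floats(0.01, 5.0), st.floats(0.01, 5.0))
    def test_total_function(self, hr_O, hr_P):
        assert interim_decision(hr_O, hr_P) in set(Decision)


EQUAL_W = CombinationWeights.from_planned_events(135, 135)


class TestCombination:
    def test_null_midpoint_not_rejected(self):
        c, rej = combination_statistic(0.5, 0.5, EQUAL_W, alpha=0.025)
        assert c == pytest.approx(0.0, abs=1e-12)
        assert not rej

    def test_closed_form_equal_small_ps(self):
        c, rej = combination_statistic(0.025, 0.025, EQUAL_W, alpha=0.025)
        assert c == pytest.approx(2 * math.sqrt(0.5) * ndtri(0.975), abs=1e-9)  # 2.7718
        assert rej

    def test_degenerate_weight_reduces_to_single_stage(self):
        w = CombinationWeights(1.0, 0.0)
        c, _ = combination_statistic(0.01, 0.7, w, alpha=0.025)
        assert c == pytest.approx(ndtri(0.99), abs=1e-9)

    def test_out_of_range_p_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clipped"):
            c, rej = combination_statistic(0.0, 0.5, EQUAL_W)
        assert np.isfinite(c)

    @given(probs, probs)
    def test_statistic_and_pvalue_scales_agree(self, p1, p2):
        """C > Phi^{-1}(1-alpha) iff the combined p-value 1-Phi(C) < alpha."""
        alpha = 0.025
        _, rej = combination_statistic(p1, p2, EQUAL_W, alpha)
        assert rej == (combination_pvalue(p1, p2, EQUAL_W) < alpha)

    def test_weights_from_unequal_information(self):
        w = CombinationWeights.from_planned_events(90, 180)
        assert w.w1 == pytest.approx(math.sqrt(1 / 3))
        assert w.w2 == pytest.approx(math.sqrt(2 / 3))

    def test_weight_scale_invariance(self):
        a = CombinationWeights.from_planned_events(135, 135)
        b = CombinationWeights.from_planned_events(27, 27)
        assert a == b

    def test_zero_stage_information_rejected(self):
        with pytest.raises(ValueError):
            CombinationWeights.from_planned_events(270, 0)


class TestHochberg:
    @pytest.mark.parametrize(
        "p_O, p_P, expected",
        [(0.01, 0.03, 0.02), (0.5, 0.5, 0.5), (0.04, 0.012, 0.024), (0.9, 0.8, 0.9)],
    )
    def test_printed_formula(self, p_O, p_P, expected):
        assert hochberg_intersection_p(p_O, p_P) == pytest.approx(expected)

    @given(probs, probs)
    def test_symmetric_bounded(self, a, b):
        p = hochberg_intersection_p(a, b)
        assert p == hochberg_intersection_p(b, a)
        assert min(a, b) <= p <= 1.0


class TestClosedTesting:
    def test_all_half_rejects_nothing(self):
        fd = closed_testing_decision(
            Decision.CONTINUE_O, EQUAL_W, 0.025,
            p1_O=0.5, p1_P=0.5, p2_O=0.5, p2_P=0.5,
        )
        assert not fd.rejected_O and not fd.rejected_P

    def test_continue_o_path_strong_evidence_rejects_both(self):
        """With all stage p-values 0.005 the intersection p is 0.01 per
        stage and every combination test passes at alpha=0.025."""
        fd = closed_testing_decision(
            Decision.CONTINUE_O, EQUAL_W, 0.025,
            p1_O=0.005, p1_P=0.005, p2_O=0.005, p2_P=0.005,
        )
        assert fd.rejected_O and fd.rejected_P

    def test_intersection_gate_blocks_elementary_rejection(self):
        """O-combination alone passing cannot reject O under closure.

        With p^O = 0.06 and p^P = 0.97 per stage, the elementary
        O-combination passes (C = 2.199 > 1.960) but the Hochberg
        intersection p is 0.12 per stage and its combination fails
        (C = 1.662), so closure blocks the rejection.
        """
        _, elementary_passes = combination_statistic(0.06, 0.06, EQUAL_W, 0.025)
        assert elementary_passes
        fd = closed_testing_decision(
            Decision.CONTINUE_O, EQUAL_W, 0.025,
            p1_O=0.06, p1_P=0.97, p2_O=0.06, p2_P=0.97,
        )
        assert not fd.rejected_O and not fd.rejected_P

    def test_enrich_path_never_rejects_overall(self):
        fd = closed_testing_decision(
            Decision.ENRICH_P, EQUAL_W, 0.025,
            p1_O=0.001, p1_P=0.001, p2_P=0.001,
        )
        assert fd.rejected_P and not fd.rejected_O

    def test_futility_rejects_nothing(self):
        fd = closed_testing_decision(Decision.FUTILITY, EQUAL_W, 0.025)
        assert not fd.rejected_O and not fd.rejected_P

    def test_missing_path_pvalues_are_contract_errors(self):
        with pytest.raises(ValueError):
            closed_testing_decision(Decision.CONTINUE_O, EQUAL_W, 0.025, p1_O=0.1, p1_P=0.1)
        with pytest.raises(ValueError):
            closed_testing_decision(Decision.ENRICH_P, EQUAL_W, 0.025, p1_O=0.1, p1_P=0.1)

    @given(probs, probs, probs, probs)
    def test_closure_monotonicity(self, p1_O, p1_P, p2_O, p2_P):
        """Rejecting any elementary hypothesis implies the intersection
        combination test passed."""
        fd = closed_testing_decision(
            Decision.CONTINUE_O, EQUAL_W, 0.025,
            p1_O=p1_O, p1_P=p1_P, p2_O=p2_O, p2_P=p2_P,
        )
        if fd.rejected_O or fd.rejected_P:
            p1_int = hochberg_intersection_p(p1_O, p1_P)
            p2_int = hochberg_intersection_p(p2_O, p2_P)
            _, rej_int = combination_statistic(p1_int, p2_int, EQUAL_W, 0.025)
            assert rej_int
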