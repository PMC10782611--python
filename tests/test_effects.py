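"""Risk-ratio reconstruction against an independent closed-form oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from preprint_concordance import (
    Direction,
    NotEstimableError,
    Outcome,
    OutcomeReport,
    direction,
    is_significant,
    risk_ratio,
)


def oracle_rr(a, n1, c, n2, alpha=0.05):
    """Independent closed-form evaluation (plain floats, no shared code path)."""
    if a == 0 and c == 0:
        return None
    if a == 0 or c == 0:
        a, c, n1, n2 = a + 0.5, c + 0.5, n1 + 1, n2 + 1
    point = (a / n1) / (c / n2)
    se = math.sqrt(1 / a - 1 / n1 + 1 / c - 1 / n2)
    z = norm.ppf(1 - alpha / 2)
    return point, math.exp(math.log(point) - z * se), math.exp(math.log(point) + z * se), se


class TestRiskRatio:
    def test_identical_arms_give_unity_and_log_symmetric_interval(self):
        est = risk_ratio(OutcomeReport(Outcome.MORTALITY_D28, 10, 100, 10, 100))
        assert est.point == pytest.approx(1.0)
        assert est.ci_low * est.ci_high == pytest.approx(1.0)

    def test_halved_risk_example(self):
        est = risk_ratio(OutcomeReport(Outcome.MORTALITY_D28, 5, 50, 10, 50))
        assert est.point == pytest.approx(0.5)
        assert est.log_se == pytest.approx(math.sqrt(0.26))
        assert est.ci_low == pytest.approx(0.18405, abs=1e-4)
        assert est.ci_high == pytest.approx(1.35831, abs=1e-4)
        assert not est.corrected

    def test_double_zero_not_estimable(self):
        est = risk_ratio(OutcomeReport(Outcome.MORTALITY_D28, 0, 50, 0, 50))
        assert not est.estimable
        assert est.point is None

    def test_single_zero_applies_continuity_correction(self):
        est = risk_ratio(OutcomeReport(Outcome.MORTALITY_D28, 0, 50, 5, 50))
        assert est.corrected
        expected = (0.5 / 51) / (5.5 / 51)
        assert est.point == pytest.approx(expected, rel=1e-12)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            risk_ratio(OutcomeReport(Outcome.MORTALITY_D28, 5, 50, 5, 50), alpha=1.5)

    def test_oracle_agreement_over_grid(self):
        """Closed-form oracle agreement to 1e-12 on >= 1000 small tables."""
        checked = 0
        for n1 in (3, 7, 12, 25, 40):
            for n2 in (4, 9, 15, 30, 50):
                for a in range(0, n1 + 1, max(1, n1 // 5)):
                    for c in range(0, n2 + 1, max(1, n2 // 5)):
                        est = risk_ratio(OutcomeReport(Outcome.MORTALITY_D28, a, n1, c, n2))
                        expected = oracle_rr(a, n1, c, n2)
                        if expected is None:
                            assert not est.estimable
                        else:
                            p, lo, hi, se = expected
                            assert est.point == pytest.approx(p, rel=1e-12)
                            assert est.ci_low == pytest.approx(lo, rel=1e-12)
                            assert est.ci_high == pytest.approx(hi, rel=1e-12)
                            assert est.log_se == pytest.approx(se, rel=1e-12)
                        checked += 1
        assert checked >= 1000

    @settings(max_examples=200, deadline=None)
    @given(
        n1=st.integers(1, 300), n2=st.integers(1, 300),
        a_frac=st.floats(0, 1), c_frac=st.floats(0, 1),
    )
    def test_arm_swap_reciprocity(self, n1, n2, a_frac, c_frac):
        a, c = round(a_frac * n1), round(c_frac * n2)
        est = risk_ratio(OutcomeReport(Outcome.MORTALITY_D28, a, n1, c, n2))
        swapped = risk_ratio(OutcomeReport(Outcome.MORTALITY_D28, c, n2, a, n1))
        assert est.estimable == swapped.estimable
        if est.estimable:
            assert swapped.point == pytest.approx(1 / est.point, rel=1e-12)
            assert swapped.ci_low == pytest.approx(1 / est.ci_high, rel=1e-12)
            assert swapped.ci_high == pytest.approx(1 / est.ci_low, rel=1e-12)

    def test_interval_narrows_with_proportional_scaling(self):
        widths = []
        for scale in (1, 2, 4, 8):
            est = risk_ratio(OutcomeReport(
                Outcome.MORTALITY_D28, 5 * scale, 50 * scale, 8 * scale, 60 * scale))
            widths.append(math.log(est.ci_high / est.ci_low))
        assert all(w2 < w1 for w1, w2 in zip(widths, widths[1:]))

    def test_significance_matches_wald_z_test(self):
        """Two-sided Wald z-test equivalence on uncorrected tables."""
        z_crit = norm.ppf(0.975)
        for a, n1, c, n2 in [(5, 50, 10, 50), (2, 200, 20, 200), (30, 60, 10, 60),
                             (7, 20, 8, 25), (1, 10, 9, 10), (15, 100, 15, 100)]:
            est = risk_ratio(OutcomeReport(Outcome.MORTALITY_D28, a, n1, c, n2))
            z = abs(math.log(est.point)) / est.log_se
            assert is_significant(est) == (z > z_crit)


class TestDirectionAndSignificance:
    def test_harm_outcome_below_one_favors_intervention(self):
        est = risk_ratio(OutcomeReport(Outcome.MORTALITY_D28, 8, 100, 10, 100))
        assert direction(est) is Direction.FAVORS_INTERVENTION

    def test_benefit_outcome_below_one_favors_control(self):
        est = risk_ratio(OutcomeReport(Outcome.CLINICAL_IMPROVEMENT_D28, 8, 100, 10, 100))
        assert direction(est) is Direction.FAVORS_CONTROL

    def test_unity_point_is_directionless(self):
        est = risk_ratio(OutcomeReport(Outcome.MORTALITY_D28, 10, 100, 10, 100))
        assert direction(est) is Direction.NULL

    def test_interval_containing_one_not_significant(self):
        est = risk_ratio(OutcomeReport(Outcome.MORTALITY_D28, 5, 50, 10, 50))
        assert not is_significant(est)

    def test_interval_excluding_one_significant(self):
        est = risk_ratio(OutcomeReport(Outcome.MORTALITY_D28, 5, 500, 50, 500))
        assert est.ci_high < 1
        assert is_significant(est)

    def test_boundary_endpoint_at_one_counts_as_not_significant(self):
        from preprint_concordance import EffectEstimate
        est = EffectEstimate(outcome=Outcome.MORTALITY_D28, point=1.2,
                             ci_low=1.0, ci_high=1.5, log_se=0.1)
        assert not is_significant(est)

    def test_predicates_reject_inestimable(self):
        est = risk_ratio(OutcomeReport(Outcome.MORTALITY_D28, 0, 50, 0, 50))
        with pytest.raises(NotEstimableError):
            direction(est)
        with pytest.raises(NotEstimableError):
            is_significant(est)
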