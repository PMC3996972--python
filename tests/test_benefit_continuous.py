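"""Continuous-marker RPB: closed forms, quadrature and Monte-Carlo cross-checks."""

import numpy as np
import pytest
from scipy.stats import norm

from popbenefit import (
    BenefitWeights,
    ContinuousPreventionProfile,
    CostCoefficient,
    StratumSet,
    ThresholdPolicy,
    TwoByTwoTable,
    calibrate_from_or,
    nb_continuous,
    par_percent_continuous,
    q_unexposed,
    rpb_adjusted_continuous,
    rpb_detection,
    rpb_detection_continuous,
    rpb_prevention_continuous,
    rpb_restricted_continuous,
    sensitivity_at,
    solve_threshold,
    specificity_at,
    total_gain_continuous,
)

W = 0.01
EA = BenefitWeights(1.0, 0.03)


@pytest.fixture
def balanced_c(pair_or50):
    return solve_threshold(pair_or50, ThresholdPolicy("balanced"))


@pytest.fixture
def fixed_spec_c(pair_or50):
    return solve_threshold(pair_or50, ThresholdPolicy("fixed_specificity", 0.95))


class TestQUnexposed:
    def test_uninformative_marker_returns_prevalence(self):
        pair = calibrate_from_or(1.0)
        for c in (-0.5, 0.0, 0.8):
            assert q_unexposed(pair, c, W) == pytest.approx(W, abs=1e-12)

    def test_balanced_anchor(self, pair_or50, balanced_c):
        assert q_unexposed(pair_or50, balanced_c, W) == pytest.approx(0.00198, abs=2e-5)

    def test_vanishes_as_sensitivity_approaches_one(self, pair_or50):
        c = pair_or50.mu_diseased - 7 * pair_or50.sigma  # sens ~ 1
        assert q_unexposed(pair_or50, c, W) < 1e-6

    def test_bounded_by_prevalence_for_informative_marker(self, pair_or50):
        for c in np.linspace(-1.0, 2.0, 15):
            q = q_unexposed(pair_or50, c, W)
            assert 0.0 <= q <= W


class TestParPercent:
    def test_uninformative_marker_zero(self):
        assert par_percent_continuous(calibrate_from_or(1.0), 0.3, W) == pytest.approx(
            0.0, abs=1e-10
        )

    def test_balanced_anchor(self, pair_or50, balanced_c):
        assert par_percent_continuous(pair_or50, balanced_c, W) == pytest.approx(
            80.17, abs=0.2
        )

    def test_limit_at_full_sensitivity(self, pair_or50):
        c = pair_or50.mu_diseased - 8 * pair_or50.sigma
        assert par_percent_continuous(pair_or50, c, W) == pytest.approx(100.0, abs=1e-4)


class TestDetectionRpb:
    def test_fixed_specificity_anchor(self, pair_or50, fixed_spec_c):
        assert round(rpb_detection_continuous(pair_or50, fixed_spec_c, W, EA), 3) == 0.119

    def test_balanced_higher_prevalence_anchor(self, pair_or50, balanced_c):
        value = rpb_detection_continuous(
            pair_or50, balanced_c, 0.03, BenefitWeights(1.0, 0.06)
        )
        assert round(value, 3) == 0.176

    def test_zero_crossing(self, pair_or50):
        """Threshold where w f1 sens equals (1-w) f2 (1-spec) gives RPB 0."""
        from scipy.optimize import brentq

        g = lambda c: rpb_detection_continuous(pair_or50, c, W, EA)
        c0 = brentq(g, -1.0, 3.0)
        assert g(c0) == pytest.approx(0.0, abs=1e-12)
        sens = sensitivity_at(pair_or50, c0)
        spec = specificity_at(pair_or50, c0)
        assert W * sens == pytest.approx((1 - W) * 0.03 * (1 - spec), rel=1e-9)

    def test_denominator_invariance_across_thresholds(self, pair_or50):
        """Numerator/RPB ratio is the constant stake w f1 + (1-w) f2 for any c."""
        expected = W * EA.f1 + (1 - W) * EA.f2
        for c in np.linspace(-0.5, 2.0, 9):
            rpb = rpb_detection_continuous(pair_or50, c, W, EA)
            num = W * EA.f1 * sensitivity_at(pair_or50, c) - (
                1 - W
            ) * EA.f2 * (1 - specificity_at(pair_or50, c))
            if abs(rpb) > 1e-15:
                assert num / rpb == pytest.approx(expected, abs=1e-12)

    def test_unique_interior_maximum(self, pair_or50):
        """Detection RPB rises then falls in c for an informative marker."""
        grid = np.linspace(-1.5, 3.0, 200)
        vals = np.array([rpb_detection_continuous(pair_or50, c, W, EA) for c in grid])
        k = int(np.argmax(vals))
        assert 0 < k < len(grid) - 1
        assert np.all(np.diff(vals[: k + 1]) > -1e-12)
        assert np.all(np.diff(vals[k:]) < 1e-12)

    def test_closed_form_matches_quadrature(self, pair_or50, fixed_spec_c):
        generic = pair_or50.to_density_pair()
        closed = rpb_detection_continuous(pair_or50, fixed_spec_c, W, EA)
        quad = rpb_detection_continuous(generic, fixed_spec_c, W, EA)
        assert quad == pytest.approx(closed, abs=1e-8)


class TestPreventionRpb:
    def test_all_zero_profile(self, pair_or50, balanced_c):
        prof = ContinuousPreventionProfile.constant(0.0, 0.0)
        assert rpb_prevention_continuous(pair_or50, balanced_c, W, EA, prof) == 0.0

    def test_full_efficacy_equals_detection_credit(self, pair_or50, balanced_c):
        prof = ContinuousPreventionProfile.constant(1.0, 0.0)
        value = rpb_prevention_continuous(pair_or50, balanced_c, W, EA, prof)
        sens = sensitivity_at(pair_or50, balanced_c)
        den = W * EA.f1 + (1 - W) * EA.f2
        assert value == pytest.approx(W * EA.f1 * sens / den, abs=1e-8)

    def test_constant_half_efficacy_closed_form(self, pair_or50, balanced_c):
        prof = ContinuousPreventionProfile.constant(0.5, 0.0)
        value = rpb_prevention_continuous(pair_or50, balanced_c, W, EA, prof)
        sens = sensitivity_at(pair_or50, balanced_c)
        assert value == pytest.approx(0.5 * W * sens / 0.0397, abs=1e-6)
        assert value == pytest.approx(0.1053, abs=3e-4)

    def test_nonnegative_without_adverse_effects(self, pair_or50):
        """delta=0 keeps prevention RPB >= 0 at every threshold and efficacy."""
        for c in (-0.5, 0.5, 1.5):
            for eta in (0.1, 0.6, 1.0):
                prof = ContinuousPreventionProfile.constant(eta, 0.0)
                assert rpb_prevention_continuous(pair_or50, c, W, EA, prof) >= 0.0

    def test_adverse_effects_can_flip_sign(self, pair_or50, balanced_c):
        prof = ContinuousPreventionProfile.constant(1.0, 0.5)
        assert rpb_prevention_continuous(pair_or50, balanced_c, W, EA, prof) < 0.0

    def test_marker_dependent_efficacy_vs_direct_quadrature(self, pair_or50, balanced_c):
        from scipy.integrate import quad

        prof = ContinuousPreventionProfile.logistic(midpoint=0.5, scale=0.3)
        value = rpb_prevention_continuous(pair_or50, balanced_c, W, EA, prof)
        integrand = lambda x: prof.eta_at(x) * pair_or50.pdf_diseased(x)
        eta_int, _ = quad(integrand, balanced_c, 6.0)
        assert value == pytest.approx(W * eta_int / 0.0397, abs=1e-7)


class TestRestrictedRpb:
    def test_full_efficacy_is_sensitivity(self, pair_or50, balanced_c):
        prof = ContinuousPreventionProfile.constant(1.0)
        value = rpb_restricted_continuous(pair_or50, balanced_c, prof)
        assert value == pytest.approx(sensitivity_at(pair_or50, balanced_c), abs=1e-9)

    def test_zero_efficacy(self, pair_or50, balanced_c):
        prof = ContinuousPreventionProfile.constant(0.0)
        assert rpb_restricted_continuous(pair_or50, balanced_c, prof) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_quadrature_vs_monte_carlo(self, pair_or50, balanced_c):
        """eta(x)=Phi(x): integral checked against sampling from the diseased density."""
        prof = ContinuousPreventionProfile(eta=lambda x: float(norm.cdf(x)))
        value = rpb_restricted_continuous(pair_or50, balanced_c, prof)
        rng = np.random.default_rng(11)
        draws = rng.normal(pair_or50.mu_diseased, pair_or50.sigma, size=200_000)
        contrib = np.where(draws > balanced_c, norm.cdf(draws), 0.0)
        mc = contrib.mean()
        se = contrib.std(ddof=1) / np.sqrt(len(draws))
        assert abs(value - mc) < 3 * se


class TestAdjustedAndGain:
    def test_adjusted_single_stratum(self, pair_or50, fixed_spec_c):
        unadj = rpb_detection_continuous(pair_or50, fixed_spec_c, W, EA)
        strata = StratumSet([1.0], [(pair_or50, fixed_spec_c, W, EA)])
        assert rpb_adjusted_continuous(strata) == pytest.approx(unadj)

    def test_adjusted_weighted_mean(self):
        strata = StratumSet([0.6, 0.4], [0.119, -0.008])
        assert rpb_adjusted_continuous(strata) == pytest.approx(0.0682)

    def test_total_gain_zero_cost_is_rpb_numerator(self, pair_or50, fixed_spec_c):
        gain = total_gain_continuous(pair_or50, fixed_spec_c, W, EA)
        rpb = rpb_detection_continuous(pair_or50, fixed_spec_c, W, EA)
        assert gain == pytest.approx(rpb * (W + (1 - W) * 0.03), abs=1e-14)

    def test_total_gain_with_cost_anchor(self, pair_or50, fixed_spec_c):
        gain = total_gain_continuous(
            pair_or50, fixed_spec_c, W, EA, cost=CostCoefficient(0.1)
        )
        # num 0.0047363 minus 0.1 * treated fraction 0.0557215
        assert gain == pytest.approx(-0.000836, abs=2e-6)

    def test_total_gain_monotone_in_h(self, pair_or50, balanced_c):
        gains = [
            total_gain_continuous(pair_or50, balanced_c, W, EA, cost=CostCoefficient(h))
            for h in (0.0, 0.01, 0.1)
        ]
        assert gains == sorted(gains, reverse=True)


class TestNetBenefit:
    def test_fixed_specificity_anchor(self, pair_or50, fixed_spec_c):
        assert round(nb_continuous(pair_or50, fixed_spec_c, W, 0.03), 3) == 0.005

    def test_zero_sensitivity_nonpositive(self, pair_or50):
        hi = pair_or50.mu_diseased + 9 * pair_or50.sigma
        assert nb_continuous(pair_or50, hi, W, 0.03) <= 1e-12

    def test_equals_rpb_numerator(self, pair_or50, balanced_c):
        nb = nb_continuous(pair_or50, balanced_c, W, EA.f2)
        rpb = rpb_detection_continuous(pair_or50, balanced_c, W, EA)
        assert nb == pytest.approx(rpb * (W + (1 - W) * EA.f2), abs=1e-14)


def test_dichotomized_marker_reproduces_binary_formulas(pair_or50, balanced_c):
    """Feeding the induced 2x2 fractions to the binary RPB matches the continuous one."""
    sens = sensitivity_at(pair_or50, balanced_c)
    spec = specificity_at(pair_or50, balanced_c)
    a = W * sens
    b = (1 - W) * (1 - spec)
    c_cell = W * (1 - sens)
    d = (1 - W) * spec
    t = TwoByTwoTable(a, b, c_cell, d)
    assert rpb_detection(t, EA) == pytest.approx(
        rpb_detection_continuous(pair_or50, balanced_c, W, EA), abs=1e-12
    )
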