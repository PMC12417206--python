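"""Beta sampling model of the proportion: standard error, shape parameters,
confidence tail, acceptance threshold, and credence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special
from scipy.stats import beta as beta_dist

from bpcredence import (
    StandardParams,
    beta_parameters,
    confidence_at,
    credence,
    proportion_standard_error,
    solve_acceptance_threshold,
)


def params_with(p_test=0.78, c_pmin=0.95):
    return StandardParams(c_pmin=c_pmin, p_test=p_test, delta=10.0, p_hat=0.85,
                          ref_mean=130.0, ref_sd=20.0)


class TestProportionStandardError:
    @pytest.mark.parametrize(
        "mu_p, n, expected",
        [(0.5, 100, 0.05), (0.913, 85, 0.030569)],
    )
    def test_matches_binomial_formula(self, mu_p, n, expected):
        assert proportion_standard_error(mu_p, n) == pytest.approx(expected, abs=1e-5)

    @pytest.mark.parametrize("mu_p, n", [(0.0, 100), (1.0, 100), (0.5, 1), (-0.1, 10)])
    def test_degenerate_inputs_rejected(self, mu_p, n):
        with pytest.raises(ValueError):
            proportion_standard_error(mu_p, n)


class TestBetaParameters:
    def test_symmetric_case_gives_half_n_minus_one(self):
        bp = beta_parameters(0.5, 101)
        assert bp.alpha == pytest.approx(50.0, abs=1e-9)
        assert bp.beta == pytest.approx(50.0, abs=1e-9)

    def test_closed_form_equals_simplified_identity(self):
        bp = beta_parameters(0.913, 85)
        assert bp.alpha == pytest.approx(84 * 0.913, abs=1e-9)
        assert bp.beta == pytest.approx(84 * 0.087, abs=1e-9)

    @given(mu_p=st.floats(0.01, 0.99), n=st.integers(2, 10_000))
    @settings(max_examples=100, derandomize=True)
    def test_moment_matching_and_simplification(self, mu_p, n):
        """The moment-matched Beta has the requested mean and SD, and its
        shapes reduce to (n-1)mu_p and (n-1)(1-mu_p)."""
        bp = beta_parameters(mu_p, n)
        assert bp.alpha == pytest.approx((n - 1) * mu_p, rel=1e-9)
        assert bp.beta == pytest.approx((n - 1) * (1 - mu_p), rel=1e-9)
        mean = bp.alpha / (bp.alpha + bp.beta)
        var = bp.alpha * bp.beta / ((bp.alpha + bp.beta) ** 2 * (bp.alpha + bp.beta + 1))
        assert mean == pytest.approx(mu_p, rel=1e-9)
        assert math.sqrt(var) == pytest.approx(bp.sigma_p, rel=1e-9)


class TestConfidenceAt:
    def test_boundaries(self):
        bp = beta_parameters(0.9, 85)
        assert confidence_at(0.0, bp) == 1.0
        assert confidence_at(1.0, bp) == pytest.approx(0.0, abs=1e-15)

    def test_non_increasing_in_p(self):
        bp = beta_parameters(0.85, 50)
        ps = np.linspace(0, 1, 101)
        vals = [confidence_at(p, bp) for p in ps]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_matches_empirical_survival_function(self, rng):
        """The analytic tail equals the survival function of Beta draws."""
        bp = beta_parameters(0.87, 85)
        draws = rng.beta(bp.alpha, bp.beta, size=1_000_000)
        for p in (0.7, 0.78, 0.85, 0.9):
            emp = np.mean(draws >= p)
            se = math.sqrt(emp * (1 - emp) / draws.size) or 1e-6
            assert confidence_at(p, bp) == pytest.approx(emp, abs=3.5 * se)

    @given(mu_p=st.floats(0.05, 0.95), n=st.integers(2, 5000), p=st.floats(0.0, 1.0))
    @settings(max_examples=150, derandomize=True)
    def test_moment_matched_form_equals_simplified_form(self, mu_p, n, p):
        """Confidence via the full moment-matching shapes equals the
        simplified (n-1)-parameterisation to near machine precision."""
        bp = beta_parameters(mu_p, n)
        via_shapes = 1.0 - special.betainc(bp.alpha, bp.beta, p)
        via_identity = 1.0 - special.betainc((n - 1) * mu_p, (n - 1) * (1 - mu_p), p)
        assert via_shapes == pytest.approx(via_identity, abs=1e-12)


class TestAcceptanceThreshold:
    def test_calibration_identity(self):
        """Plugging the solved threshold back in returns the required confidence."""
        params = params_with()
        for n in (30, 85, 255, 3077):
            m = solve_acceptance_threshold(n, params)
            assert params.p_test < m < 1.0
            c = confidence_at(params.p_test, beta_parameters(m, n))
            assert c == pytest.approx(params.c_pmin, abs=1e-8)

    def test_threshold_decreases_with_sample_size(self):
        params = params_with()
        t = [solve_acceptance_threshold(n, params) for n in (30, 85, 300)]
        assert t[0] > t[1] > t[2]

    def test_large_n_limit_approaches_test_proportion(self):
        params = params_with()
        assert solve_acceptance_threshold(10**6, params) == pytest.approx(
            params.p_test, abs=1e-3)

    def test_monte_carlo_tail_probability_at_threshold(self, rng):
        """At the solved threshold, the chance of falling below p_test is 5%."""
        params = params_with()
        n = 85
        m = solve_acceptance_threshold(n, params)
        draws = rng.beta((n - 1) * m, (n - 1) * (1 - m), size=1_000_000)
        below = np.mean(draws < params.p_test)
        assert below == pytest.approx(1 - params.c_pmin, abs=3.5 * math.sqrt(0.05 * 0.95 / 1e6))

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            solve_acceptance_threshold(1, params_with())


class TestCredence:
    def test_zero_threshold_gives_certainty(self):
        assert credence(0.6, 0.0, 50) == 1.0

    def test_degenerate_proportion_uses_point_mass_convention(self):
        assert credence(1.0, 0.9, 50) == 1.0
        assert credence(0.0, 0.5, 50) == 0.0

    def test_monotone_in_observed_proportion(self):
        mus = np.linspace(0.6, 0.99, 40)
        vals = [credence(m, 0.8484, 85) for m in mus]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_monotone_in_threshold(self):
        thresholds = np.linspace(0.0, 1.0, 41)
        vals = [credence(0.9, t, 85) for t in thresholds]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_matches_beta_tail_mass(self, rng):
        """Credence equals the fraction of Beta draws above the threshold."""
        n, mu_p, m = 85, 0.913, 0.8484
        draws = rng.beta((n - 1) * mu_p, (n - 1) * (1 - mu_p), size=1_000_000)
        emp = np.mean(draws >= m)
        se = math.sqrt(emp * (1 - emp) / draws.size)
        assert credence(mu_p, m, n) == pytest.approx(emp, abs=3.5 * se)

    def test_equals_scipy_beta_survival(self):
        n, mu_p, m = 85, 0.913, 0.8484
        assert credence(mu_p, m, n) == pytest.approx(
            beta_dist.sf(m, (n - 1) * mu_p, (n - 1) * (1 - mu_p)), abs=1e-12)
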