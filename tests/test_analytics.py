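"""Closed-form distributions: frozen values, oracles, and invariants.

Independent oracles used here:

* brute-force convolution of the zero-truncated Poisson PMF (for the
  size-given-duration law),
* the alternating inclusion-exclusion surjection sum (small s only),
* an ordered-set-partition generating identity,
  sum_d d! {s d} e^(-r d) = (1 - x) sum_k k^s x^k with x = 1/(1 + e^r),
  which gives the size PMF without any Stirling recurrence,
* mpmath high-precision Stirling numbers,
* adaptive quadrature of the rate-superposition integral.
"""

import math

import mpmath
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq, minimize_scalar
from scipy.special import gammaln, logsumexp

import avapoiss as ap
from avapoiss import analytics as an

E = math.e


def log_size_pmf_oracle(s: int, r: float) -> float:
    """ln P_S(s) via the ordered-set-partition identity (no Stirling table)."""
    x = 1.0 / (1.0 + math.exp(r))
    k = np.arange(1, max(20 * s, 200))
    inner = logsumexp(s * np.log(k) + k * math.log(x))
    return (s * math.log(r) - gammaln(s + 1) - math.log(math.expm1(r))
            + math.log1p(-x) + inner)


class TestDurationPmf:
    def test_frozen_value(self):
        assert an.hpp_duration_pmf(1, 1.0) == pytest.approx(1 / E, rel=1e-12)

    def test_geometric_ratio(self):
        d = np.arange(1, 30)
        ratio = an.hpp_duration_pmf(d + 1, 0.7) / an.hpp_duration_pmf(d, 0.7)
        assert np.allclose(ratio, 1 - np.exp(-0.7), rtol=1e-12)

    def test_normalization(self):
        total = an.hpp_duration_pmf(np.arange(1, 3000), 1.0).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_iei_bin_form_is_rate_free_r1(self):
        d = np.arange(1, 20)
        assert np.allclose(an.hpp_duration_pmf_at_iei_bin(d), an.hpp_duration_pmf(d, 1.0))
        assert an.hpp_duration_pmf_at_iei_bin(1) == pytest.approx(1 / E)

    @given(st.floats(min_value=0.05, max_value=4.0), st.floats(min_value=0.05, max_value=4.0))
    @settings(max_examples=50, deadline=None)
    def test_mu_strictly_decreasing(self, r1, r2):
        # flatter duration distributions at higher rates
        if r1 == r2:
            return
        lo, hi = sorted((r1, r2))
        assert an.mu_decay(lo) > an.mu_decay(hi)

    def test_invalid_duration(self):
        with pytest.raises(ValueError):
            an.hpp_duration_pmf(0, 1.0)


class TestTruncatedPoisson:
    def test_frozen_value(self):
        assert an.truncated_poisson_pmf(1, 1.0) == pytest.approx(1 / (E - 1), rel=1e-12)

    def test_normalization_and_mean(self):
        a = np.arange(1, 200)
        pmf = an.truncated_poisson_pmf(a, 1.0)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-10)
        # (1 - e^-r) <a> = r
        assert np.dot(a, pmf) == pytest.approx(1.0 / (1 - np.exp(-1.0)), rel=1e-10)


class TestSizeGivenDuration:
    def test_d1_reduces_to_truncated_poisson(self):
        assert an.hpp_size_given_duration_pmf(2, 1, 1.0) == pytest.approx(
            1 / (2 * (E - 1)), rel=1e-12
        )

    def test_forced_single_event_configuration(self):
        # s = d: every bin exactly one event, (r/(e^r-1))^d
        assert an.hpp_size_given_duration_pmf(2, 2, 1.0) == pytest.approx(
            (1 / (E - 1)) ** 2, rel=1e-12
        )

    def test_impossible_configuration_is_zero(self):
        assert an.hpp_size_given_duration_pmf(2, 3, 1.0) == 0.0

    @pytest.mark.parametrize("r", [0.5, 1.0, 2.0])
    def test_matches_convolution_oracle(self, r):
        # d-fold convolution of the zero-truncated Poisson
        a = an.truncated_poisson_pmf(np.arange(1, 31), r)
        conv = a.copy()
        for d in range(1, 7):
            if d > 1:
                conv = np.convolve(conv, a)
            for s in range(d, 31):
                oracle = conv[s - d] if s - d < conv.size else 0.0
                assert an.hpp_size_given_duration_pmf(s, d, r) == pytest.approx(
                    oracle, abs=1e-10
                )

    def test_alternating_sum_route_small_s(self):
        # inclusion-exclusion surjection count; safe only at small s
        for s in range(1, 25):
            for d in range(1, min(s, 6) + 1):
                u = sum((-1) ** i * math.comb(d, i) * (d - i) ** s for i in range(d + 1))
                direct = (1.0**s) * u / (math.factorial(s) * math.expm1(1.0) ** d)
                assert an.hpp_size_given_duration_pmf(s, d, 1.0) == pytest.approx(
                    direct, abs=1e-9
                )

    def test_stirling_table_against_mpmath(self):
        table = an.log_stirling2(60)
        for s, d in [(10, 3), (25, 7), (40, 15), (60, 30), (60, 5)]:
            exact = mpmath.log(mpmath.stirling2(s, d))
            assert table[s, d] == pytest.approx(float(exact), rel=1e-10)


class TestSizePmf:
    def test_frozen_values(self):
        assert an.hpp_size_pmf(1, 1.0) == pytest.approx(np.exp(-1) / (E - 1), rel=1e-10)
        assert an.hpp_size_pmf(2, 1.0) == pytest.approx(0.18581061531021345, rel=1e-10)

    @pytest.mark.parametrize("r", [0.5, 1.0, 2.0])
    def test_normalization(self, r):
        total = an.hpp_size_pmf(np.arange(1, 700), r).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("r,s", [(0.5, 20), (1.0, 40), (2.0, 60)])
    def test_matches_generating_identity_oracle(self, r, s):
        assert an.hpp_log_size_pmf(s, r)[0] == pytest.approx(
            log_size_pmf_oracle(s, r), abs=1e-9
        )

    def test_monotone_below_r2_peak_above(self):
        low = an.hpp_size_pmf(np.arange(1, 101), 0.5)
        assert (np.diff(low) < 0).all()
        high = an.hpp_size_pmf(np.arange(1, 101), 3.0)
        assert np.argmax(high) > 0  # global maximum at s > 1 for r > 2

    def test_tail_slope_matches_generating_identity(self):
        # the exact asymptotic decay of the size tail at r = 0.01, measured
        # on s in [800, 1200], against the independent generating-function
        # route evaluated at the endpoints
        lp = an.hpp_log_size_pmf(np.arange(800, 1201), 0.01)
        slope = -np.mean(np.diff(lp))
        oracle = -(log_size_pmf_oracle(1200, 0.01) - log_size_pmf_oracle(800, 0.01)) / 400
        assert slope == pytest.approx(oracle, rel=1e-6)
        # closed-form slope of the dominant-term analysis: -ln r + ln ln(1+e^r)
        assert slope == pytest.approx(-np.log(0.01) + np.log(np.log(1 + np.exp(0.01))), rel=0.01)


class TestTailApprox:
    def test_printed_anchors(self):
        t = an.hpp_tail_decay(0.01, 1000)
        assert round(t.b_value) == -2
        assert t.rate_bound == pytest.approx(0.046, abs=0.001)

    def test_lambda_substitution(self):
        t = an.hpp_tail_decay(0.01, 1000)
        assert t.decay == pytest.approx(-np.log(0.01) - 1 + t.b_value, rel=1e-12)
        assert t.valid

    def test_validity_flag_flips_at_bound(self):
        bound = an.hpp_tail_decay(0.01, 1000).rate_bound
        assert an.hpp_tail_decay(bound * 0.9, 1000).valid
        assert not an.hpp_tail_decay(bound * 1.1, 1000).valid


class TestSummaries:
    def test_frozen_values_at_r1(self):
        s = an.hpp_summaries(1.0)
        assert s.mean_duration == pytest.approx(E, rel=1e-12)
        assert s.mean_size == pytest.approx(4.30026, abs=1e-4)
        assert s.avalanche_rate == pytest.approx(0.23254, abs=1e-4)

    @given(st.floats(min_value=0.05, max_value=5.0))
    @settings(max_examples=50, deadline=None)
    def test_event_conservation_identity(self, r):
        s = an.hpp_summaries(r)
        assert s.avalanche_rate * s.mean_size == pytest.approx(r, rel=1e-12)

    def test_mean_duration_matches_series(self):
        d = np.arange(1, 4000)
        series = np.dot(d, an.hpp_duration_pmf(d, 1.0))
        assert an.hpp_summaries(1.0).mean_duration == pytest.approx(series, abs=1e-8)


class TestQAnalytic:
    def test_frozen_value(self):
        assert an.q_analytic(1.0) == pytest.approx(0.767, abs=0.001)

    def test_unit_crossing_near_1_5(self):
        root = brentq(lambda x: an.q_analytic(x) - 1.0, 0.5, 3.0)
        assert root == pytest.approx(1.5, abs=0.05)

    def test_maximum_near_3_75(self):
        res = minimize_scalar(lambda x: -an.q_analytic(x), bounds=(1, 10), method="bounded")
        assert res.x == pytest.approx(3.75, abs=0.05)

    def test_limits(self):
        assert an.q_analytic(1e-6) < 1e-4
        assert an.q_analytic(1e4) == pytest.approx(1.0, abs=1e-3)
        assert an.q_analytic(1e4) > 1.0  # approaches unity from above
        # asymptotic branch continuous with the exact branch
        assert an.q_analytic(699.0) == pytest.approx(an.q_analytic(701.0), rel=1e-4)


class TestRateWeight:
    def test_constant_regime(self):
        assert an.rate_weight(5.0, 2.0) == pytest.approx(1.01, abs=0.01)

    def test_small_rate_regime(self):
        w = an.rate_weight(0.01, 2.0)
        assert w == pytest.approx(468, rel=0.01)
        assert w == pytest.approx(100 * np.log(100), rel=0.05)  # ~ (1/r) ln(1/r)

    def test_beta1_positive(self):
        r = np.geomspace(1e-3, 10, 50)
        assert (an.rate_weight(r, 1.0) > 0).all()


class TestWindowedDurationPmf:
    def test_wide_window_recovers_pure_power_law(self):
        d = np.arange(10, 101)
        ratio = an.windowed_duration_pmf(d, 2.0, 1e-8, 50.0) / d**-2.0
        assert ratio.max() / ratio.min() < 1.01

    def test_matches_quadrature_of_superposition_integral(self):
        # d^-beta window == integral of w(r) e^-2r (1-e^-r)^d dr, up to one
        # global constant (here the change of variables is exact, so the
        # constant is 1)
        for d in (1, 2, 5, 10, 30, 100, 300):
            ig, _ = quad(
                lambda r: an.rate_weight(r, 2.0) * np.exp(-2 * r) * (1 - np.exp(-r)) ** d,
                0.01, 5.0, limit=400,
            )
            assert an.windowed_duration_pmf(d, 2.0, 0.01, 5.0) == pytest.approx(
                ig, rel=0.005
            )

    def test_compensated_plot_shows_both_cutoffs(self):
        # d^2 P_D(d) is flat mid-range with smooth suppression on both ends;
        # at these bounds the right cutoff (from r1) dominates while the left
        # one (from r2) is mild, so the curve peaks at an interior d
        d = np.arange(1, 301)
        comp = d**2.0 * an.windowed_duration_pmf(d, 2.0, 0.01, 5.0)
        mid = comp[20:60]
        assert mid.max() / mid.min() < 1.3            # flat mid-range
        peak = int(np.argmax(comp))
        assert 1 < peak < 100                          # interior maximum
        assert comp[0] < comp[peak]                    # suppressed small-d end
        assert comp[-1] < 0.7 * mid.mean()             # suppressed tail

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            an.windowed_duration_pmf(5, 2.0, 1.0, 0.5)


class TestMixture:
    def test_point_mass_reproduces_hpp_exactly(self):
        res = an.ipp_mixture((np.array([1.0]), np.array([1.0])), max_s=30, max_d=30)
        assert np.allclose(res.size_pmf, an.hpp_size_pmf(res.sizes, 1.0), rtol=1e-12)
        assert np.allclose(res.duration_pmf, an.hpp_duration_pmf(res.durations, 1.0), rtol=1e-12)
        assert res.fano == pytest.approx(1.0, rel=1e-12)
        slope = an.hpp_summaries(1.0).size_by_duration_slope
        assert np.allclose(res.mean_size_by_duration, slope * res.durations, rtol=1e-12)

    def test_four_rate_fano(self, four_rate_mixture_nodes):
        res = an.ipp_mixture(four_rate_mixture_nodes, max_s=5, max_d=5)
        assert res.fano == pytest.approx(1.605, abs=0.001)

    def test_four_rate_duration_matches_simulation(self, four_rate_series, four_rate_mixture_nodes):
        res = an.ipp_mixture(four_rate_mixture_nodes, max_s=5, max_d=200)
        emp = ap.avalanche_distributions(ap.extract_avalanches(four_rate_series)).duration
        tv = 0.5 * np.abs(emp.pmf(res.durations) - res.duration_pmf).sum()
        assert tv < 0.02

    def test_continuous_weighting_matches_windowed_form(self):
        rw = ap.RateWeighting(beta=2.0, r1=0.01, r2=5.0)
        res = an.ipp_mixture(rw, max_s=5, max_d=150)
        wd = an.windowed_duration_pmf(res.durations.astype(float), 2.0, 0.01, 5.0)
        ratio = res.duration_pmf / wd
        assert ratio.max() / ratio.min() < 1.001  # equal up to one global constant

    def test_invalid_weighting(self):
        with pytest.raises(ValueError):
            an.ipp_mixture((np.array([1.0, 2.0]), np.array([1.0])))
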