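"""Tail probabilities of chi-square(1) mixtures: closed forms, independent
oracles (Imhof quadrature, Monte Carlo), approximation quality, and the
automatic precision-escalation logic."""

import math

import mpmath as mp
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.integrate import quad

from genescore.lincomb import (
    ConvergenceError,
    DomainError,
    LinCombSpec,
    PrecisionPolicy,
    sf_auto,
    sf_davies,
    sf_pearson3,
    sf_ruben,
    sf_saddlepoint,
    sf_satterthwaite,
)


def imhof_sf(lam, q):
    """Independent oracle: Gil-Pelaez/Imhof real-axis inversion (f64 quadrature).

    Im[e^{-iqu} prod(1-2i lam u)^{-1/2}] = sin(theta0 - qu)/rho with
    theta0 = (1/2) sum arctan(2 lam u), rho = prod(1+4 lam^2 u^2)^{1/4}.
    """
    lam = np.asarray(lam, dtype=float)

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(2.0 * lam * u)) - q * u
        rho = np.prod((1.0 + 4.0 * lam**2 * u**2) ** 0.25)
        return math.sin(theta) / (u * rho)

    # head: dense panels; tail: half-period panels summed with iterated
    # averaging (Euler-style acceleration of the alternating series)
    u0 = 20.0 / max(q, 1.0)
    val = 0.0
    for a, b in zip(*(lambda e: (e[:-1], e[1:]))(np.linspace(0.0, u0, 120))):
        val += quad(integrand, a, b, limit=200)[0]
    h = math.pi / q
    terms = np.array(
        [quad(integrand, u0 + k * h, u0 + (k + 1) * h, limit=100)[0] for k in range(60)]
    )
    partial = np.cumsum(terms)
    while partial.size > 1:
        partial = 0.5 * (partial[1:] + partial[:-1])
    return 0.5 + (val + float(partial[0])) / math.pi


class TestSpecAndPolicy:
    def test_zero_coefficients_dropped(self):
        assert LinCombSpec([1.0, 0.0, 2.0]).coefficients == (1.0, 2.0)

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            LinCombSpec([0.0])
        with pytest.raises(ValueError):
            LinCombSpec([1.0, math.inf])

    def test_all_positive_flag(self):
        assert LinCombSpec([0.1, 2.0]).all_positive
        assert not LinCombSpec([0.1, -0.2]).all_positive

    def test_policy_validation(self):
        with pytest.raises(ValueError):
            PrecisionPolicy(initial_digits=10)
        with pytest.raises(ValueError):
            PrecisionPolicy(max_digits=10)
        with pytest.raises(ValueError):
            PrecisionPolicy(tail_floor=2.0)


class TestRuben:
    def test_chi2_1_closed_form(self):
        assert sf_ruben(LinCombSpec([1.0]), 1.0) == pytest.approx(
            0.3173105078629141, abs=1e-14
        )

    def test_exponential_closed_form(self):
        # 2*chi2_2 is Exponential with mean 4
        assert sf_ruben(LinCombSpec([2.0, 2.0]), 4.0) == pytest.approx(
            math.exp(-1.0), rel=1e-12
        )

    def test_against_imhof_oracle(self):
        # oracle sanity: it must reproduce the chi2_1 closed form first
        assert imhof_sf([1.0], 1.0) == pytest.approx(0.3173105078629141, abs=1e-9)
        lam = [0.6, 0.3, 0.1]
        assert sf_ruben(LinCombSpec(lam), 5.0) == pytest.approx(
            imhof_sf(lam, 5.0), abs=1e-8
        )

    def test_rejects_negative_coefficients(self):
        with pytest.raises(DomainError, match="sf_davies"):
            sf_ruben(LinCombSpec([1.0, -0.5]), 1.0)

    def test_q_nonpositive_is_one(self):
        assert sf_ruben(LinCombSpec([1.0, 2.0]), 0.0) == 1.0

    def test_beta_option(self):
        spec = LinCombSpec([0.6, 0.3, 0.1])
        default = sf_ruben(spec, 5.0)
        assert sf_ruben(spec, 5.0, beta=0.1) == pytest.approx(default, rel=1e-12)
        with pytest.raises(ValueError):
            sf_ruben(spec, 5.0, beta=0.5)  # >= 2*lambda_min

    def test_high_precision_value(self):
        v = sf_ruben(LinCombSpec([1.0]), 1.0, digits=40)
        with mp.workdps(60):
            truth = mp.erfc(1 / mp.sqrt(2))
            assert abs(v - truth) / truth < mp.mpf(10) ** -38


class TestDavies:
    def test_symmetric_median_at_zero(self):
        assert sf_davies(LinCombSpec([0.5, -0.5]), 0.0) == pytest.approx(0.5, abs=1e-10)

    def test_agrees_with_ruben_on_positive_spec(self):
        assert sf_davies(LinCombSpec([1.0]), 1.0) == pytest.approx(
            0.3173105078629141, abs=1e-12
        )

    def test_mixed_sign_against_monte_carlo(self):
        lam = np.array([0.7, 0.2, -0.4])
        rng = np.random.default_rng(42)
        draws = rng.standard_normal((2_000_000, 3)) ** 2 @ lam
        mc = float(np.mean(draws > 1.5))
        se = math.sqrt(mc * (1 - mc) / draws.size)
        assert abs(sf_davies(LinCombSpec(lam), 1.5) - mc) < 3 * se

    def test_left_tail_by_symmetry(self):
        spec = LinCombSpec([0.5, -0.5])
        p = sf_davies(spec, 1.0)
        assert sf_davies(spec, -1.0) == pytest.approx(1.0 - p, abs=1e-12)

    def test_product_normal_bessel_oracle(self):
        # P(z*w > 1) for independent standard normals = (1/pi) int_1^inf K0
        from scipy.special import k0

        oracle = quad(k0, 1, np.inf)[0] / math.pi
        assert sf_davies(LinCombSpec([0.5, -0.5]), 1.0) == pytest.approx(
            oracle, abs=1e-9
        )

    def test_all_negative_coefficients(self):
        assert sf_davies(LinCombSpec([-1.0, -0.5]), 0.5) == 0.0
        assert sf_davies(LinCombSpec([-1.0]), -1.0) == pytest.approx(
            stats.chi2.cdf(1.0, 1), rel=1e-10
        )

    def test_high_precision_matches_ruben(self):
        spec = LinCombSpec([0.6, 0.3, 0.1])
        r = sf_ruben(spec, 8.0, digits=30)
        d = sf_davies(spec, 8.0, digits=30)
        with mp.workdps(50):
            assert abs(r - d) / r < mp.mpf(10) ** -28


class TestMomentApproximations:
    def test_satterthwaite_exact_for_equal_coefficients(self):
        assert sf_satterthwaite(LinCombSpec([1.0, 1.0]), 5.991) == pytest.approx(
            stats.chi2.sf(5.991, 2), rel=1e-14
        )
        assert sf_satterthwaite(LinCombSpec([1.0]), 3.0) == pytest.approx(
            stats.chi2.sf(3.0, 1), rel=1e-14
        )

    def test_satterthwaite_overestimates_significance_in_far_tail(self):
        # skewed spectrum, deep tail: moment matching is anti-conservative
        spec = LinCombSpec([0.9, 0.1])
        exact = sf_ruben(spec, 4.0)
        approx = sf_satterthwaite(spec, 4.0)
        assert approx < exact
        spec2 = LinCombSpec([0.9, 0.05, 0.05])
        q = 15.0
        assert sf_satterthwaite(spec2, q) < sf_ruben(spec2, q)

    def test_pearson_exact_single_and_equal(self):
        assert sf_pearson3(LinCombSpec([1.0]), 2.0) == pytest.approx(
            0.15729920705028105, rel=1e-12
        )
        assert sf_pearson3(LinCombSpec([0.3] * 4), 2.5) == pytest.approx(
            stats.chi2.sf(2.5 / 0.3, 4), rel=1e-10
        )

    def test_pearson_against_exact_on_mixed_spectrum(self):
        # three-moment matching is decent at moderate depth but, like all
        # moment methods, drifts anti-conservative deep in the tail
        spec = LinCombSpec([0.6, 0.3, 0.1])
        exact_mid = float(sf_ruben(spec, 3.0, digits=30))
        assert sf_pearson3(spec, 3.0) == pytest.approx(exact_mid, rel=0.05)
        exact_deep = float(sf_ruben(spec, 8.0, digits=30))
        approx_deep = sf_pearson3(spec, 8.0)
        assert approx_deep == pytest.approx(exact_deep, rel=0.25)
        assert approx_deep < exact_deep

    def test_domain_errors(self):
        for fn in (sf_satterthwaite, sf_pearson3):
            with pytest.raises(DomainError):
                fn(LinCombSpec([1.0, -1.0]), 1.0)


class TestSaddlepoint:
    def test_chi2_3_within_one_percent(self):
        v = sf_saddlepoint(LinCombSpec([1.0, 1.0, 1.0]), 7.8147279)
        assert v == pytest.approx(stats.chi2.sf(7.8147279, 3), rel=0.01)

    def test_chi2_1_far_tail_within_five_percent(self):
        v = sf_saddlepoint(LinCombSpec([1.0]), 30.0)
        assert v == pytest.approx(stats.chi2.sf(30.0, 1), rel=0.05)

    def test_continuity_at_the_mean(self):
        spec = LinCombSpec([0.5, 0.5])
        at_mean = sf_saddlepoint(spec, 1.0)
        nearby = 0.5 * (sf_saddlepoint(spec, 1.0001) + sf_saddlepoint(spec, 0.9999))
        assert at_mean == pytest.approx(nearby, abs=1e-6)

    @pytest.mark.parametrize("lam", [[0.9, 0.05, 0.05], [0.6, 0.3, 0.1], [1, 1, 0.1]])
    def test_accuracy_across_tail_depths(self, lam):
        spec = LinCombSpec(lam)
        for p_target in (1e-2, 1e-5, 1e-8):
            q = _q_at(spec, p_target)
            exact = float(sf_ruben(spec, q, digits=20))
            assert sf_saddlepoint(spec, q) == pytest.approx(exact, rel=0.05)

    def test_mixed_sign_supported(self):
        spec = LinCombSpec([0.7, 0.2, -0.4])
        assert sf_saddlepoint(spec, 1.5) == pytest.approx(
            sf_davies(spec, 1.5), rel=0.06
        )


def _q_at(spec, p_target):
    from scipy import optimize

    return optimize.brentq(
        lambda q: math.log(max(float(sf_ruben(spec, q, digits=14)), 1e-300))
        - math.log(p_target),
        1e-6,
        3000.0,
    )


class TestAutoSwitching:
    def test_exact_hint_reports_provenance(self):
        res = sf_auto(LinCombSpec([1.0]), 1.0, method_hint="exact")
        assert res.p == pytest.approx(0.3173105078629141, rel=1e-12)
        assert res.method in ("ruben", "davies")
        assert res.digits == 15 and not res.flagged

    def test_saddle_default_for_positive(self):
        res = sf_auto(LinCombSpec([1.0, 0.5]), 2.0)
        assert res.method == "saddlepoint"

    def test_mixed_sign_routed_to_davies_regardless_of_hint(self):
        for hint in ("auto", "exact", "saddle"):
            res = sf_auto(LinCombSpec([0.3, -0.7]), 2.0, method_hint=hint)
            assert res.method == "davies"

    def test_escalation_resolves_extreme_tail(self):
        res = sf_auto(LinCombSpec([1.0]), 400.0, method_hint="exact")
        assert res.digits > 15 and not res.flagged
        with mp.workdps(120):
            truth = mp.erfc(mp.mpf(20) / mp.sqrt(2))
            assert abs(res.p_raw - truth) / truth < mp.mpf(10) ** -30
        # log10(p) stays finite even though p underflows nothing here
        assert res.log10p == pytest.approx(-88.259, abs=0.01)

    def test_auto_falls_back_to_exact_in_deep_tail(self):
        res = sf_auto(LinCombSpec([1.0]), 400.0, method_hint="auto")
        assert res.method == "ruben" and res.digits > 15


class TestInvariants:
    @given(
        st.lists(st.floats(0.05, 3.0), min_size=1, max_size=8),
        st.floats(0.05, 4.0),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_ruben_davies_cross_agreement(self, lam, qscale):
        spec = LinCombSpec(lam)
        q = qscale * sum(lam)
        r = sf_ruben(spec, q, digits=13)
        d = sf_davies(spec, q, digits=13)
        assert 0.0 <= r <= 1.0 and 0.0 <= d <= 1.0
        # requested 13 digits, plus an absolute floor at f64 rounding noise
        assert abs(r - d) <= 1e-12 * max(r, 1e-12) + 5e-15

    @given(st.lists(st.floats(0.1, 2.0), min_size=1, max_size=6))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_sf_nonincreasing_in_q(self, lam):
        spec = LinCombSpec(lam)
        qs = np.linspace(0.01, 4.0 * sum(lam), 12)
        for fn in (lambda s, q: sf_ruben(s, q), sf_satterthwaite, sf_saddlepoint):
            vals = [fn(spec, q) for q in qs]
            assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("n", [1, 2, 5, 10])
    @pytest.mark.parametrize("c", [0.1, 1.0, 10.0])
    def test_equal_coefficient_specs_match_chi2(self, n, c):
        spec = LinCombSpec([c] * n)
        for p_target in (1e-10, 1e-4, 0.5):
            q = c * stats.chi2.isf(p_target, n)
            v = float(sf_ruben(spec, q, digits=30))
            assert v == pytest.approx(p_target, rel=1e-12)

    def test_monte_carlo_random_specs(self):
        rng = np.random.default_rng(3)
        for _ in range(4):
            k = int(rng.integers(2, 7))
            lam = rng.uniform(0.1, 1.5, k) * rng.choice([1, 1, 1, -1], k)
            draws = rng.standard_normal((1_000_000, k)) ** 2 @ lam
            q = float(np.quantile(draws, 0.99))
            mc = float(np.mean(draws > q))
            se = math.sqrt(mc * (1 - mc) / draws.size)
            assert abs(sf_davies(LinCombSpec(lam), q) - mc) <= 3 * se
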