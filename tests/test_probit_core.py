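"""Probit machinery: approximate link, rectangles, GHK vs independent
oracles, cutpoint/simplex bijection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from mvplc.data_io import TestDefinition
from mvplc.probit_core import (Rectangle, approx_probit_cdf,
                               approx_probit_ppf, cutpoints_to_simplex,
                               probit_max_abs_deviation, rectangle_prob,
                               response_to_rectangle, simplex_to_cutpoints)


class TestApproxProbit:
    def test_symmetry_point(self):
        assert approx_probit_cdf(0.0) == pytest.approx(0.5)

    def test_max_deviation_matches_printed_value(self):
        # the 1.702-scaled logistic deviates from the normal CDF by at
        # most 0.0095 (to 4 dp)
        assert round(probit_max_abs_deviation(), 4) == 0.0095

    def test_five_is_effectively_perfect(self):
        # the perfect-gold-standard device mu = 5 means ~100% sensitivity
        assert approx_probit_cdf(5.0) == pytest.approx(1 / (1 + np.exp(-8.51)))
        assert approx_probit_cdf(5.0) > 0.9997

    @given(st.floats(-30, 30), st.floats(-30, 30))
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_antisymmetric(self, x, y):
        if x < y:
            assert approx_probit_cdf(x) <= approx_probit_cdf(y)
        assert approx_probit_cdf(-x) == pytest.approx(
            1.0 - approx_probit_cdf(x), abs=1e-12)

    @given(st.floats(-8, 8))
    @settings(max_examples=50, deadline=None)
    def test_deviation_bounded_everywhere(self, x):
        assert abs(norm.cdf(x) - approx_probit_cdf(x)) <= 0.0096

    @given(st.floats(0.001, 0.999))
    @settings(max_examples=30, deadline=None)
    def test_ppf_inverts_cdf(self, q):
        assert approx_probit_cdf(approx_probit_ppf(q)) == pytest.approx(q)


class TestResponseToRectangle:
    def test_dichotomous_positive_is_upper_half_line(self):
        t = TestDefinition("a", 2)
        r = response_to_rectangle(1, t)
        assert (r.lower[0], r.upper[0]) == (0.0, np.inf)
        r = response_to_rectangle(0, t)
        assert (r.lower[0], r.upper[0]) == (-np.inf, 0.0)

    def test_ordinal_intervals(self):
        t = TestDefinition("w", 3)
        cuts = [-0.5, 0.7]
        assert response_to_rectangle(1, t, cuts).upper[0] == -0.5
        mid = response_to_rectangle(2, t, cuts)
        assert (mid.lower[0], mid.upper[0]) == (-0.5, 0.7)
        top = response_to_rectangle(3, t, cuts)
        assert (top.lower[0], top.upper[0]) == (0.7, np.inf)

    def test_errors(self):
        t = TestDefinition("w", 3)
        with pytest.raises(ValueError, match="needs cutpoints"):
            response_to_rectangle(1, t)
        with pytest.raises(ValueError, match="strictly increasing"):
            response_to_rectangle(1, t, [0.5, -0.5])
        with pytest.raises(ValueError, match="must be 1"):
            response_to_rectangle(4, t, [-0.5, 0.5])
        with pytest.raises(ValueError, match="0/1"):
            response_to_rectangle(2, TestDefinition("a", 2))


def _random_corr(rng, T):
    A = rng.normal(size=(T, T))
    C = A @ A.T + 0.5 * np.eye(T)
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


class TestRectangleProb:
    def test_univariate_symmetric(self):
        p = rectangle_prob(([0.0], [np.inf]), [0.0], np.eye(1))
        assert p == pytest.approx(0.5, abs=1e-10)

    def test_independent_orthant(self):
        p = rectangle_prob(([0, 0], [np.inf, np.inf]), [0, 0], np.eye(2))
        assert p == pytest.approx(0.25, abs=1e-8)

    @pytest.mark.parametrize("eps", [0.5, -0.3, 0.9])
    def test_bivariate_orthant_closed_form(self, eps):
        # P(Z1>0, Z2>0) = 1/4 + arcsin(eps) / (2 pi)
        C = np.array([[1, eps], [eps, 1.0]])
        closed = 0.25 + np.arcsin(eps) / (2 * np.pi)
        ghk = rectangle_prob(([0, 0], [np.inf, np.inf]), [0, 0], C, nodes=32)
        orc = rectangle_prob(([0, 0], [np.inf, np.inf]), [0, 0], C,
                             method="oracle")
        assert ghk == pytest.approx(closed, abs=1e-4)
        assert orc == pytest.approx(closed, abs=1e-6)

    def test_ghk_matches_oracle_on_random_instances(self):
        # randomized T <= 3 rectangles: sequential conditioning agrees
        # with independent nested quadrature
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(200):
            T = rng.integers(1, 4)
            C = _random_corr(rng, T)
            nu = rng.uniform(-3, 3, T)
            lo = rng.uniform(-3, 1, T)
            hi = lo + rng.uniform(0.3, 4, T)
            lo[rng.uniform(size=T) < 0.3] = -np.inf
            hi[rng.uniform(size=T) < 0.3] = np.inf
            g = rectangle_prob((lo, hi), nu, C, nodes=24)
            o = rectangle_prob((lo, hi), nu, C, method="oracle")
            worst = max(worst, abs(g - o))
        assert worst <= 1e-4

    def test_mc_ghk_with_uniform_draws(self):
        rng = np.random.default_rng(7)
        C = np.array([[1, 0.6], [0.6, 1.0]])
        u = rng.uniform(size=(4000, 2))
        mc = rectangle_prob(([0, 0], [np.inf, np.inf]), [0, 0], C, u=u)
        closed = 0.25 + np.arcsin(0.6) / (2 * np.pi)
        assert mc == pytest.approx(closed, abs=0.02)

    def test_total_probability_over_responses(self):
        # summing P(rectangle) over every legal joint response gives 1
        rng = np.random.default_rng(5)
        C = _random_corr(rng, 2)
        nu = rng.normal(size=2)
        cuts = np.sort(rng.normal(size=2))
        tests = [TestDefinition("a", 2), TestDefinition("w", 3)]
        total = 0.0
        for ya in (0, 1):
            for yw in (1, 2, 3):
                ra = response_to_rectangle(ya, tests[0])
                rw = response_to_rectangle(yw, tests[1], cuts)
                total += rectangle_prob(
                    (np.r_[ra.lower, rw.lower], np.r_[ra.upper, rw.upper]),
                    nu, C, nodes=24)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_ghk_order_invariance(self):
        rng = np.random.default_rng(9)
        C = _random_corr(rng, 3)
        nu = rng.normal(size=3)
        lo = np.array([-np.inf, -0.5, 0.2])
        hi = np.array([0.3, 1.0, np.inf])
        p1 = rectangle_prob((lo, hi), nu, C, nodes=48)
        perm = [2, 0, 1]
        p2 = rectangle_prob((lo[perm], hi[perm]), nu[perm],
                            C[np.ix_(perm, perm)], nodes=48)
        assert p1 == pytest.approx(p2, abs=1e-5)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="positive definite"):
            rectangle_prob(([0, 0], [1, 1]), [0, 0],
                           np.array([[1, 1.2], [1.2, 1]]))
        with pytest.raises(ValueError, match="empty rectangle"):
            Rectangle([1.0], [0.0])


class TestCutpointSimplex:
    def test_uniform_simplex(self):
        cuts = approx_probit_ppf([1 / 3, 2 / 3])
        simplex = cutpoints_to_simplex(cuts)
        assert simplex == pytest.approx([1 / 3, 1 / 3, 1 / 3])

    def test_k2_reduces_to_single_threshold(self):
        simplex = cutpoints_to_simplex([0.4])
        assert simplex == pytest.approx(
            [approx_probit_cdf(0.4), 1 - approx_probit_cdf(0.4)])

    @given(st.lists(st.floats(-2.5, 2.5), min_size=1, max_size=4,
                    unique=True), st.floats(-1, 1))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, cuts, anchor):
        cuts = np.sort(cuts)
        if np.any(np.diff(cuts) < 1e-3):
            return
        simplex = cutpoints_to_simplex(cuts, anchor)
        back = simplex_to_cutpoints(simplex, anchor)
        assert np.allclose(back, cuts, atol=1e-10)

    def test_rejects_non_monotone(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            cutpoints_to_simplex([1.0, 0.5])
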