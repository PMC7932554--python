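"""Hypothesis tests: wheat reference values, degenerate cases, properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pathdecomp as pdp

from conftest import random_system


class TestBartlett:
    def test_wheat_chi_square(self, wheat_fit):
        res = pdp.bartlett_independence_test(wheat_fit)
        assert res.statistic == pytest.approx(121.44, abs=0.1)
        assert res.df == (9,)
        assert res.stars == "**"

    def test_independent_blocks_give_zero_statistic(self, independent_system):
        res = pdp.bartlett_independence_test(pdp.fit(independent_system))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)


class TestEquationF:
    @pytest.mark.parametrize("alpha, expected", [(1, 37.9188), (3, 14.408)])
    def test_wheat_f_statistics(self, wheat_fit, alpha, expected):
        res = pdp.equation_f_test(wheat_fit, alpha)
        assert res.statistic == pytest.approx(expected, rel=0.01)
        assert res.df == (3, 101)
        assert res.stars == "**"

    def test_zero_r2_gives_f_zero(self, independent_system):
        res = pdp.equation_f_test(pdp.fit(independent_system), 1)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_index_out_of_range(self, wheat_fit):
        with pytest.raises(IndexError):
            pdp.equation_f_test(wheat_fit, 4)


class TestCoefficientT:
    @pytest.mark.parametrize(
        "j, alpha, expected, stars",
        [
            (1, 1, 6.8994, "**"),
            (3, 3, 5.4202, "**"),
            # two-sided p for t = 2.352 on 101 df is 0.021: one star
            (2, 2, 2.3527, "*"),
            (3, 2, 3.5101, "**"),
        ],
    )
    def test_wheat_t_statistics_within_one_percent(self, wheat_fit, j, alpha, expected, stars):
        # printed values come from 3-decimal inputs; agreement is ~1%
        res = pdp.coefficient_t_test(wheat_fit, j, alpha)
        assert res.statistic == pytest.approx(expected, rel=0.01)
        assert res.stars == stars

    def test_zero_coefficient_gives_t_zero(self, independent_system):
        res = pdp.coefficient_t_test(pdp.fit(independent_system), 1, 1)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)


class TestRowWilks:
    def test_wheat_lambda_first_predictor(self, wheat_fit):
        res = pdp.row_wilks_test(wheat_fit, 1)
        assert res.extras["lambda"] == pytest.approx(0.659, abs=0.01)
        assert res.df == (2, 200)

    def test_lambda_determinant_oracle(self, wheat_fit):
        # independent route: Lambda = det(E) / det(E + H_j) assembled by hand
        sys_ = wheat_fit.system
        for j in range(3):
            b_row = wheat_fit.b_star[j]
            H = np.outer(b_row, b_row) / np.diag(np.linalg.inv(sys_.Rxx))[j]
            E = sys_.Ryy - wheat_fit.b_star.T @ sys_.Rxy
            lam = np.linalg.det(E) / np.linalg.det(E + H)
            res = pdp.row_wilks_test(wheat_fit, j + 1)
            assert res.extras["lambda"] == pytest.approx(lam, abs=1e-12)

    def test_zero_row_gives_lambda_one(self):
        R = np.eye(5)
        R[1, 3] = R[3, 1] = 0.4  # x2 predicts y1; x1 predicts nothing
        sys_ = pdp.build_system(R, 50, ["x1", "x2"], ["y1", "y2", "y3"])
        res = pdp.row_wilks_test(pdp.fit(sys_), 1)
        assert res.extras["lambda"] == pytest.approx(1.0, abs=1e-12)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(seed=st.integers(0, 10_000), j=st.integers(1, 3))
    def test_lambda_is_a_likelihood_ratio(self, seed, j):
        res = pdp.row_wilks_test(pdp.fit(random_system(seed)), j)
        assert 0.0 < res.extras["lambda"] <= 1.0

    def test_exact_transform_mode(self, wheat_fit):
        res = pdp.row_wilks_test(wheat_fit, 1, exact_transform=True)
        nu = 105 - 3 - 1
        assert res.df == (3, nu - 3 + 1)
        lam = res.extras["lambda"]
        assert res.statistic == pytest.approx((nu - 3 + 1) / 3 * (1 - lam) / lam)


class TestDecisionT:
    @pytest.mark.parametrize("j, alpha, expected", [(2, 2, 4.5633), (1, 1, -3.39774)])
    def test_wheat_decision_t(self, wheat_fit, j, alpha, expected):
        dec = pdp.decision_coefficients(wheat_fit, alpha)[j - 1]
        res = pdp.decision_t_test(wheat_fit, j, alpha, dec.value)
        assert res.statistic == pytest.approx(expected, rel=0.01)
        assert res.stars == "**"

    def test_zero_decision_coefficient_gives_t_zero(self, wheat_fit):
        res = pdp.decision_t_test(wheat_fit, 1, 1, 0.0)
        assert res.statistic == 0.0

    def test_orthogonal_predictors_have_undefined_denominator(self):
        # with Rxx = I the direct effect equals the total correlation exactly
        R = np.eye(3)
        R[0, 2] = R[2, 0] = 0.5
        sys_ = pdp.build_system(R, 50, ["x1", "x2"], ["y1"])
        f = pdp.fit(sys_)
        res = pdp.decision_t_test(f, 1, 1, 0.25)
        assert res.status == "undefined"
        assert math.isnan(res.statistic)


class TestGeneralizedDecisionT:
    def test_wheat_sign_and_stars(self, wheat_fit):
        dec = pdp.generalized_decision(wheat_fit, 1)
        assert dec.test.statistic < 0
        assert dec.test.stars == "**"

    def test_zero_value_gives_t_zero(self, wheat_fit):
        res = pdp.generalized_decision_t_test(wheat_fit, 1, 0.0)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_closed_form_partials_match_finite_differences(self, wheat_fit):
        """The delta-method gradient equals numerical differentiation of the
        theta-weighted term sum with respect to each path coefficient."""
        sys_ = wheat_fit.system
        theta = wheat_fit.theta
        Rxx = sys_.Rxx
        m, p = sys_.m, sys_.p

        def term_sum(b, j):
            total = 0.0
            for a in range(p):
                total += theta[a, a] * (
                    b[j, a] ** 2
                    + sum(2 * b[j, a] * Rxx[j, k] * b[k, a] for k in range(m) if k != j)
                )
            for a in range(p):
                for t in range(a + 1, p):
                    total += theta[a, t] * (
                        2 * b[j, a] * b[j, t]
                        + sum(
                            2 * b[j, a] * Rxx[j, k] * b[k, t]
                            + 2 * b[k, a] * Rxx[k, j] * b[j, t]
                            for k in range(m)
                            if k != j
                        )
                    )
            return total

        h = 1e-6
        for j in range(m):
            closed = 2.0 * (theta @ sys_.Rxy[j, :])
            for a in range(p):
                bp = wheat_fit.b_star.copy()
                bm = wheat_fit.b_star.copy()
                bp[j, a] += h
                bm[j, a] -= h
                fd = (term_sum(bp, j) - term_sum(bm, j)) / (2 * h)
                assert closed[a] == pytest.approx(fd, abs=1e-6)

    def test_saturated_trace_rejected(self, wheat_fit):
        saturated = type(wheat_fit).__new__(type(wheat_fit))
        with pytest.raises(ValueError, match="tr"):
            # construct a shallow stand-in with trB >= 1
            object.__setattr__(saturated, "system", wheat_fit.system)
            object.__setattr__(saturated, "trB", 1.0)
            object.__setattr__(saturated, "theta", wheat_fit.theta)
            object.__setattr__(saturated, "c_diag", wheat_fit.c_diag)
            pdp.generalized_decision_t_test(saturated, 1, 0.5)


class TestProperties:
    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_statistics_invariant_under_relabeling(self, seed):
        sys_ = random_system(seed)
        f = pdp.fit(sys_)
        renamed = pdp.build_system(
            sys_.R, sys_.n, [f"a_{s}" for s in sys_.names_x], [f"b_{s}" for s in sys_.names_y]
        )
        f2 = pdp.fit(renamed)
        for j in range(1, 4):
            for a in range(1, 4):
                r1 = pdp.coefficient_t_test(f, j, a)
                r2 = pdp.coefficient_t_test(f2, j, a)
                assert r1.statistic == pytest.approx(r2.statistic, abs=1e-14)

    def test_monotonicity_of_p_values(self, wheat_fit):
        # larger |t| at fixed df -> smaller p
        small = pdp.decision_t_test(wheat_fit, 1, 1, 0.1)
        big = pdp.decision_t_test(wheat_fit, 1, 1, 0.4)
        assert abs(big.statistic) > abs(small.statistic)
        assert big.p_value < small.p_value

    def test_star_thresholds(self):
        from pathdecomp.inference import stars_for

        assert stars_for(0.005) == "**"
        assert stars_for(0.03) == "*"
        assert stars_for(0.2) == ""
        assert stars_for(0.01) == "*"
        assert stars_for(0.05) == ""
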