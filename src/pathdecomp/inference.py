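"""Hypothesis tests for the standardized multivariate regression.

Four regression-level tests plus the t-tests attached to the per-response
and generalized decision coefficients.  All statistics live on the
correlation scale, where the raw sums-of-squares (n-1) factors cancel:
the residual variance of response alpha enters as (1 - R(alpha)^2)/(n-m-1)
and the Gauss multiplier c_jj is the j-th diagonal entry of inv(Rxx).

Degenerate denominators never raise inside a batch: the returned
:class:`TestResult` carries ``status="undefined"`` (statistic NaN) or
``status="warning"`` (infinite statistic, p pinned at 0) instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import config
from .model_core import StandardizedFit

__all__ = [
    "TestResult",
    "stars_for",
    "bartlett_independence_test",
    "equation_f_test",
    "coefficient_t_test",
    "row_wilks_test",
    "decision_t_test",
    "generalized_decision_t_test",
]


def stars_for(p_value: float) -> str:
    """Significance flag: ``**`` below 0.01, ``*`` below 0.05, else empty."""
    if math.isnan(p_value):
        return ""
    if p_value < config.ALPHA_DOUBLE_STAR:
        return "**"
    if p_value < config.ALPHA_STAR:
        return "*"
    return ""


@dataclass(frozen=True)
class TestResult:
    """Outcome of one named hypothesis test.

    ``df`` is a 1- or 2-tuple (chi-square vs F/t); ``extras`` holds named
    auxiliaries such as the Wilks lambda; ``status`` is ``"ok"`` unless the
    statistic was degenerate.
    """

    name: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    stars: str
    extras: dict[str, float] = field(default_factory=dict)
    status: str = "ok"
    message: str = ""

    @property
    def significant(self) -> bool:
        return self.status == "ok" and self.p_value < config.ALPHA_STAR


def _result(name, statistic, df, p_value, *, extras=None, status="ok", message=""):
    p_value = float(min(max(p_value, 0.0), 1.0)) if not math.isnan(p_value) else p_value
    return TestResult(
        name=name,
        statistic=float(statistic),
        df=tuple(float(d) for d in df),
        p_value=p_value,
        stars=stars_for(p_value),
        extras=dict(extras or {}),
        status=status,
        message=message,
    )


def bartlett_independence_test(fit: StandardizedFit) -> TestResult:
    """Bartlett's approximate chi-square test of X/Y block independence.

    V = -(n - 1 - (p + m + 1)/2) * ln(v_xy), referred to chi-square on
    p*m degrees of freedom.  v_xy is the likelihood-ratio statistic from
    the fit; v_xy = 1 (empty association) gives V = 0, v_xy = 0 (perfect
    dependence) an infinite statistic flagged with a warning status.
    """
    sys_ = fit.system
    n, m, p = sys_.n, sys_.m, sys_.p
    scale = n - 1 - (p + m + 1) / 2.0
    df = (p * m,)
    if fit.v_xy <= 0.0:
        return _result(
            "bartlett_independence",
            math.inf,
            df,
            0.0,
            status="warning",
            message="v_xy = 0: perfect dependence, statistic infinite",
        )
    V = -scale * math.log(fit.v_xy)
    p_value = stats.chi2.sf(V, df[0])
    return _result("bartlett_independence", V, df, p_value, extras={"v_xy": fit.v_xy})


def equation_f_test(fit: StandardizedFit, alpha_index: int) -> TestResult:
    """Overall F test of the standardized equation for response alpha.

    F = (R(alpha)^2 / m) / ((1 - R(alpha)^2) / (n - m - 1)) on
    (m, n - m - 1) degrees of freedom.  ``alpha_index`` is 1-based.
    """
    sys_ = fit.system
    n, m = sys_.n, sys_.m
    r2 = float(fit.r2_alpha[_check_index(alpha_index, sys_.p, "alpha_index")])
    df = (m, n - m - 1)
    if r2 >= 1.0:
        return _result(
            "equation_F", math.inf, df, 0.0, status="warning",
            message="R(alpha)^2 = 1: saturated equation",
        )
    F = (r2 / m) / ((1.0 - r2) / (n - m - 1))
    return _result("equation_F", F, df, stats.f.sf(F, *df), extras={"r2": r2})


def coefficient_t_test(fit: StandardizedFit, j: int, alpha_index: int) -> TestResult:
    """Two-sided t test of a single path coefficient b*_{j,alpha}.

    t = b* / sqrt(c_jj * (1 - R(alpha)^2) / (n - m - 1)) on n - m - 1
    degrees of freedom.  Indices are 1-based.
    """
    sys_ = fit.system
    n, m = sys_.n, sys_.m
    ji = _check_index(j, m, "j")
    ai = _check_index(alpha_index, sys_.p, "alpha_index")
    dof = n - m - 1
    se = math.sqrt(fit.c_diag[ji] * (1.0 - fit.r2_alpha[ai]) / dof)
    b = float(fit.b_star[ji, ai])
    if se == 0.0:
        return _result(
            "coefficient_t", math.nan, (dof,), math.nan, status="undefined",
            message="zero standard error",
        )
    t = b / se
    return _result("coefficient_t", t, (dof,), 2.0 * stats.t.sf(abs(t), dof))


def row_wilks_test(fit: StandardizedFit, j: int, *, exact_transform: bool = False) -> TestResult:
    """Wilks-lambda test that predictor j contributes nothing to any response.

    The hypothesis sum-of-products matrix is the rank-one
    H_j = outer(b_j, b_j) / c_jj with b_j the j-th row of the coefficient
    matrix, and Lambda = det(E) / det(E + H_j) with E = Ryy - U the
    correlation-scale residual matrix.

    Two F transforms of Lambda are offered.  The default reports
    F = (n - m - 2) * (1 - Lambda)/Lambda on (2, 2(n - m - 2)) degrees of
    freedom.  With ``exact_transform=True`` the textbook exact transform for
    a single hypothesis degree of freedom is used instead:
    F = ((nu - p + 1)/p) * (1 - Lambda)/Lambda on (p, nu - p + 1) with
    nu = n - m - 1.
    """
    sys_ = fit.system
    n, m, p = sys_.n, sys_.m, sys_.p
    ji = _check_index(j, m, "j")
    b_row = fit.b_star[ji, :]
    H = np.outer(b_row, b_row) / fit.c_diag[ji]
    det_E = float(np.linalg.det(fit.E))
    det_EH = float(np.linalg.det(fit.E + H))
    if det_EH <= 0.0:
        raise np.linalg.LinAlgError("E + H_j is singular; Wilks lambda undefined")
    lam = det_E / det_EH
    lam = min(max(lam, 0.0), 1.0)
    if exact_transform:
        nu = n - m - 1
        df = (p, nu - p + 1)
        scale = (nu - p + 1) / p
    else:
        df = (2, 2 * (n - m - 2))
        scale = n - m - 2
    if lam == 0.0:
        return _result(
            "row_wilks_F", math.inf, df, 0.0, extras={"lambda": lam},
            status="warning", message="Lambda = 0",
        )
    F = scale * (1.0 - lam) / lam
    return _result("row_wilks_F", F, df, stats.f.sf(F, *df), extras={"lambda": lam})


def decision_t_test(fit: StandardizedFit, j: int, alpha_index: int, R_dec: float) -> TestResult:
    """t test of a per-response decision coefficient R_alpha(j).

    t = R_alpha(j) / (2 |r_jy - b*| * sqrt(c_jj (1 - R(alpha)^2)/(n-m-1)))
    on n - m - 1 degrees of freedom.  When the total correlation equals the
    direct effect exactly (no indirect channel) the denominator vanishes and
    the result is returned with ``status="undefined"``.
    """
    sys_ = fit.system
    n, m = sys_.n, sys_.m
    ji = _check_index(j, m, "j")
    ai = _check_index(alpha_index, sys_.p, "alpha_index")
    dof = n - m - 1
    r_jy = float(sys_.Rxy[ji, ai])
    b = float(fit.b_star[ji, ai])
    denom = 2.0 * abs(r_jy - b) * math.sqrt(fit.c_diag[ji] * (1.0 - fit.r2_alpha[ai]) / dof)
    if denom == 0.0:
        return _result(
            "decision_t", math.nan, (dof,), math.nan, status="undefined",
            message="r_jy equals b* exactly: zero denominator",
        )
    t = float(R_dec) / denom
    return _result("decision_t", t, (dof,), 2.0 * stats.t.sf(abs(t), dof))


def generalized_decision_t_test(fit: StandardizedFit, j: int, R_gen_dec: float) -> TestResult:
    """t test of a generalized decision coefficient R_y(j).

    The delta-method standard error uses the closed-form partial derivatives
    of R_y(j) with respect to the path coefficients of predictor j,

        dR_y(j)/db*_{j,alpha} = 2 * sum_t theta[alpha, t] * r_{j, y_t},

    obtained by differentiating the theta-weighted division term sum and
    simplifying with the normal equations.  Then

        t = R_y(j) / sqrt( sum_alpha (dR)^2 * c_jj (1 - tr(B)) / (n-m-1) )

    on n - m - 1 degrees of freedom.  Requires tr(B) < 1.
    """
    sys_ = fit.system
    n, m, p = sys_.n, sys_.m, sys_.p
    ji = _check_index(j, m, "j")
    if fit.trB >= 1.0:
        raise ValueError(f"tr(B) = {fit.trB:.6g} >= 1: residual variance basis invalid")
    dof = n - m - 1
    r_jy = sys_.Rxy[ji, :]
    dR = 2.0 * (fit.theta @ r_jy)
    denom = math.sqrt(float(dR @ dR) * fit.c_diag[ji] * (1.0 - fit.trB) / dof)
    if denom == 0.0:
        return _result(
            "generalized_decision_t", math.nan, (dof,), math.nan, status="undefined",
            message="zero delta-method variance",
        )
    t = float(R_gen_dec) / denom
    return _result("generalized_decision_t", t, (dof,), 2.0 * stats.t.sf(abs(t), dof))


def _check_index(idx: int, bound: int, what: str) -> int:
    idx = int(idx)
    if not 1 <= idx <= bound:
        raise IndexError(f"{what} = {idx} out of range 1..{bound}")
    return idx - 1
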