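"""One-to-multiple path analysis: per-response correlation and determination
division, and per-response decision coefficients.

For a single response y_alpha, every total correlation r_{j, y_alpha}
splits along the normal equations into a direct effect b*_{j,alpha} and
m - 1 indirect effects r_{jk} b*_{k,alpha} routed through correlated
predictors; the squared multiple correlation R(alpha)^2 splits into squared
direct determinations and doubled pair determinations
2 b*_j r_jk b*_k.  The decision coefficient
R_alpha(j) = 2 b* r - b*^2 collects every determination term touching
predictor j, giving a signed measure of its comprehensive influence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


from . import config, inference
from .inference import TestResult
from .model_core import StandardizedFit

__all__ = [
    "PathType",
    "PathTerm",
    "DecisionResult",
    "CorrelationEffect",
    "decompose_correlation",
    "decompose_determination",
    "decision_coefficients",
]


class PathType(enum.Enum):
    """The five path types of the multiple-to-multiple model.

    Arrow sketches (alpha and t are distinct responses, j and k distinct
    predictors):

    * DIRECT_SAME   — y_a <- x_j -> y_a
    * CORR_SAME     — y_a <- x_j <-> x_k -> y_a
    * DIRECT_CROSS  — y_a <- x_j -> y_t
    * CORR_CROSS_JK — y_a <- x_j <-> x_k -> y_t
    * CORR_CROSS_KJ — y_a <- x_k <-> x_j -> y_t
    """

    DIRECT_SAME = "direct_same"
    CORR_SAME = "corr_same"
    DIRECT_CROSS = "direct_cross"
    CORR_CROSS_JK = "corr_cross_jk"
    CORR_CROSS_KJ = "corr_cross_kj"

    @property
    def is_cross(self) -> bool:
        return self in (PathType.DIRECT_CROSS, PathType.CORR_CROSS_JK, PathType.CORR_CROSS_KJ)

    @property
    def is_corr(self) -> bool:
        return self in (PathType.CORR_SAME, PathType.CORR_CROSS_JK, PathType.CORR_CROSS_KJ)


@dataclass(frozen=True)
class PathTerm:
    """One additive term of a decomposition, tagged with its path type.

    Indices are 1-based to match the field's subscript conventions.  ``k``
    is present only for correlation-mediated (CORR_*) types, ``t`` only for
    cross-response (*_CROSS) types.  ``weighted_value`` carries the
    theta-weighted contribution when the term takes part in the division of
    tr(B); it is None elsewhere.
    """

    path_type: PathType
    j: int
    alpha: int
    value: float
    k: int | None = None
    t: int | None = None
    weighted_value: float | None = None

    def __post_init__(self) -> None:
        if self.path_type.is_corr:
            if self.k is None or self.k == self.j:
                raise ValueError(f"{self.path_type} requires k distinct from j")
        elif self.k is not None:
            raise ValueError(f"{self.path_type} takes no k index")
        if self.path_type.is_cross:
            if self.t is None or self.t == self.alpha:
                raise ValueError(f"{self.path_type} requires t distinct from alpha")
        elif self.t is not None:
            raise ValueError(f"{self.path_type} takes no t index")


@dataclass(frozen=True)
class CorrelationEffect:
    """Division of one total correlation r_{j, y_alpha}.

    total = direct + sum of indirects, exactly, by the normal equations.
    ``residual_path`` is sqrt(1 - R(alpha)^2), the path from the equation
    residual into y_alpha, attached once per response.
    """

    j: int
    alpha: int
    direct: PathTerm
    indirects: tuple[PathTerm, ...]
    total: float
    residual_path: float

    @property
    def indirect_total(self) -> float:
        return float(sum(t.value for t in self.indirects))


@dataclass(frozen=True)
class DecisionResult:
    """A decision coefficient with its components, test, rank and label.

    ``scope`` is "per_response" (value = R_alpha(j), components sum to it)
    or "generalized" (value = part_I + part_II).  ``classification`` follows
    the sign/significance rule: a significantly negative coefficient marks a
    restrictive factor, a significantly positive one a positive decision
    factor, anything else is nonsignificant.
    """

    scope: str
    j: int
    value: float
    components: tuple[PathTerm, ...]
    test: TestResult
    rank: int
    classification: str
    alpha: int | None = None
    part_I: float | None = None
    part_II: float | None = None


def _classify(value: float, test: TestResult, level: float) -> str:
    significant = test.status == "ok" and test.p_value < level
    if significant and value > 0:
        return "positive_decision"
    if significant and value < 0:
        return "restrictive"
    return "nonsignificant"


def _rank_descending(values: list[float]) -> list[int]:
    # ties broken by ascending j (stable sort on original order)
    order = sorted(range(len(values)), key=lambda i: (-values[i], i))
    ranks = [0] * len(values)
    for pos, i in enumerate(order, start=1):
        ranks[i] = pos
    return ranks


def decompose_correlation(fit: StandardizedFit, alpha_index: int) -> list[CorrelationEffect]:
    """Split every total correlation with response alpha into direct and
    indirect effects.

    Returns one :class:`CorrelationEffect` per predictor j, whose direct
    term is b*_{j,alpha} and whose m - 1 indirect terms are
    r_{jk} b*_{k,alpha}.  ``alpha_index`` is 1-based.
    """
    sys_ = fit.system
    ai = _idx(alpha_index, sys_.p, "alpha_index")
    m = sys_.m
    resid = float(fit.residual_paths[ai])
    out = []
    for j in range(m):
        direct = PathTerm(PathType.DIRECT_SAME, j + 1, alpha_index, float(fit.b_star[j, ai]))
        indirects = tuple(
            PathTerm(
                PathType.CORR_SAME,
                j + 1,
                alpha_index,
                float(sys_.Rxx[j, k] * fit.b_star[k, ai]),
                k=k + 1,
            )
            for k in range(m)
            if k != j
        )
        total = direct.value + sum(t.value for t in indirects)
        out.append(
            CorrelationEffect(
                j=j + 1,
                alpha=alpha_index,
                direct=direct,
                indirects=indirects,
                total=total,
                residual_path=resid,
            )
        )
    return out


def decompose_determination(fit: StandardizedFit, alpha_index: int) -> list[PathTerm]:
    """Split R(alpha)^2 into m squared direct terms and C(m, 2) pair terms.

    Direct terms are b*_{j,alpha}^2; each unordered pair (j, k), j < k, is
    stored once with the full doubled value 2 b*_j r_jk b*_k (report
    renderers show it under both orderings, as the field's tables do).
    The values sum to R(alpha)^2.
    """
    sys_ = fit.system
    ai = _idx(alpha_index, sys_.p, "alpha_index")
    m = sys_.m
    b = fit.b_star[:, ai]
    terms = [
        PathTerm(PathType.DIRECT_SAME, j + 1, alpha_index, float(b[j] ** 2)) for j in range(m)
    ]
    for j in range(m):
        for k in range(j + 1, m):
            terms.append(
                PathTerm(
                    PathType.CORR_SAME,
                    j + 1,
                    alpha_index,
                    float(2.0 * b[j] * sys_.Rxx[j, k] * b[k]),
                    k=k + 1,
                )
            )
    return terms


def decision_coefficients(
    fit: StandardizedFit,
    alpha_index: int,
    *,
    level: float = config.ALPHA_CLASSIFY,
) -> list[DecisionResult]:
    """Per-response decision coefficients R_alpha(j) for every predictor.

    R_alpha(j) = 2 b*_{j,alpha} r_{j,y_alpha} - b*_{j,alpha}^2, identically
    equal (through the normal equations) to the sum of the determination
    terms touching predictor j: its squared direct term plus the full
    doubled pair terms with every other predictor.  Each coefficient carries
    its t test, a descending-value rank and a classification at ``level``.
    """
    sys_ = fit.system
    ai = _idx(alpha_index, sys_.p, "alpha_index")
    m = sys_.m
    b = fit.b_star[:, ai]
    results: list[tuple[float, tuple[PathTerm, ...]]] = []
    for j in range(m):
        comps = [PathTerm(PathType.DIRECT_SAME, j + 1, alpha_index, float(b[j] ** 2))]
        for k in range(m):
            if k == j:
                continue
            comps.append(
                PathTerm(
                    PathType.CORR_SAME,
                    j + 1,
                    alpha_index,
                    float(2.0 * b[j] * sys_.Rxx[j, k] * b[k]),
                    k=k + 1,
                )
            )
        value = float(2.0 * b[j] * sys_.Rxy[j, ai] - b[j] ** 2)
        results.append((value, tuple(comps)))
    ranks = _rank_descending([v for v, _ in results])
    out = []
    for j, ((value, comps), rank) in enumerate(zip(results, ranks), start=1):
        test = inference.decision_t_test(fit, j, alpha_index, value)
        out.append(
            DecisionResult(
                scope="per_response",
                j=j,
                alpha=alpha_index,
                value=value,
                components=comps,
                test=test,
                rank=rank,
                classification=_classify(value, test, level),
            )
        )
    return out


def _idx(idx: int, bound: int, what: str) -> int:
    idx = int(idx)
    if not 1 <= idx <= bound:
        raise IndexError(f"{what} = {idx} out of range 1..{bound}")
    return idx - 1
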