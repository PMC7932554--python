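"""Multiple-to-multiple layer: cross-response correlation decomposition,
theta-weighted division of tr(B), and generalized decision coefficients.

The part of each response-response correlation carried by the common
predictors is U[alpha, t] = b*_alpha' Rxx b*_t, and it decomposes into
exactly m^2 composite path terms: m direct terms b*_{j,alpha} b*_{j,t} and
two correlation-mediated terms per unordered predictor pair.  Weighting
every same-response and cross-response determination term by the matching
entry theta[alpha, t] of inv(Ryy) divides the generalized determination
coefficient in its trace approximation, tr(B); collecting the weighted
terms that touch one predictor gives its generalized decision coefficient
R_y(j) = R_y(j)_I (same-response part) + R_y(j)_II (cross-response part).

Stored term values follow the doubled convention of the field's printed
tables: pair terms carry the factor 2 and cross direct terms are
2 b*_{j,alpha} b*_{j,t}, so a rendered cell equals the stored value.  The
conservation checks account for this.
"""

from __future__ import annotations

from dataclasses import dataclass


from . import config, inference
from .model_core import StandardizedFit
from .path_one import DecisionResult, PathTerm, PathType, _classify, _rank_descending

__all__ = [
    "CrossDecomposition",
    "cross_correlation_decomposition",
    "generalized_r2_division",
    "generalized_decision",
    "rank_decisions",
]


@dataclass(frozen=True)
class CrossDecomposition:
    """The m^2-term division of one X-mediated cross correlation U[alpha, t].

    Direct terms are stored doubled (2 b_j,alpha b_j,t) per printed-table
    convention, and each unordered predictor pair contributes both ordered
    terms, so the *undoubled* sum of the stored values equals U[alpha, t]:
    sum(value) / 2 == U[alpha, t].
    """

    alpha: int
    t: int
    terms: tuple[PathTerm, ...]
    total: float

    @property
    def doubled_total(self) -> float:
        """Sum of the stored (doubled) term values, equal to 2 U[alpha, t]."""
        return float(sum(term.value for term in self.terms))


def cross_correlation_decomposition(
    fit: StandardizedFit, alpha_index: int, t_index: int
) -> CrossDecomposition:
    """Decompose the X-mediated correlation between responses alpha and t.

    Emits m DIRECT_CROSS terms 2 b*_{j,a} b*_{j,t} and, per unordered
    predictor pair (j, k), a CORR_CROSS_JK term 2 b*_{j,a} r_jk b*_{k,t}
    and a CORR_CROSS_KJ term 2 b*_{k,a} r_kj b*_{j,t} — m^2 terms in all.
    Requires ``alpha_index < t_index`` (use ``decompose_determination`` for
    a response with itself).
    """
    sys_ = fit.system
    p, m = sys_.p, sys_.m
    ai = _idx(alpha_index, p, "alpha_index")
    ti = _idx(t_index, p, "t_index")
    if ai == ti:
        raise ValueError(
            "alpha_index equals t_index; same-response determination is "
            "decomposed by path_one.decompose_determination"
        )
    if ai > ti:
        raise ValueError("require alpha_index < t_index")
    ba = fit.b_star[:, ai]
    bt = fit.b_star[:, ti]
    terms: list[PathTerm] = [
        PathTerm(
            PathType.DIRECT_CROSS, j + 1, alpha_index,
            float(2.0 * ba[j] * bt[j]), t=t_index,
        )
        for j in range(m)
    ]
    for j in range(m):
        for k in range(j + 1, m):
            r_jk = sys_.Rxx[j, k]
            terms.append(
                PathTerm(
                    PathType.CORR_CROSS_JK, j + 1, alpha_index,
                    float(2.0 * ba[j] * r_jk * bt[k]), k=k + 1, t=t_index,
                )
            )
            terms.append(
                PathTerm(
                    PathType.CORR_CROSS_KJ, j + 1, alpha_index,
                    float(2.0 * ba[k] * r_jk * bt[j]), k=k + 1, t=t_index,
                )
            )
    return CrossDecomposition(
        alpha=alpha_index, t=t_index, terms=tuple(terms), total=float(fit.U[ai, ti])
    )


def generalized_r2_division(fit: StandardizedFit) -> list[PathTerm]:
    """Divide tr(B) along the five path types, theta-weighted.

    Same-response terms (from each R(alpha)^2 decomposition) are weighted
    by theta[alpha, alpha]; cross-response terms for each pair alpha < t by
    theta[alpha, t].  Every term carries both its raw (printed-convention)
    value and its theta-weighted contribution; the weighted values sum to
    tr(B) exactly because

        tr(B) = sum_a theta_aa R(a)^2 + 2 sum_{a<t} theta_at U[a, t].

    Correlation pairs are stored once per unordered pair: same-response
    pairs with the doubled value 2 b_j r_jk b_k, and cross-response pairs
    with the combined both-orderings value
    2 b_{j,a} r_jk b_{k,t} + 2 b_{k,a} r_kj b_{j,t} (tagged CORR_CROSS_JK
    with j < k), mirroring the paired vector entries of the division
    formula.  The term count is therefore p*m*(m+1)*(p+1)/4.
    """
    from .path_one import decompose_determination

    sys_ = fit.system
    m, p = sys_.m, sys_.p
    theta = fit.theta
    b = fit.b_star
    Rxx = sys_.Rxx
    out: list[PathTerm] = []
    for a in range(p):
        w = float(theta[a, a])
        for term in decompose_determination(fit, a + 1):
            out.append(_with_weight(term, w * term.value))
    for a in range(p):
        for t in range(a + 1, p):
            w = float(theta[a, t])
            for j in range(m):
                direct = PathTerm(
                    PathType.DIRECT_CROSS, j + 1, a + 1,
                    float(2.0 * b[j, a] * b[j, t]), t=t + 1,
                )
                out.append(_with_weight(direct, w * direct.value))
            for j in range(m):
                for k in range(j + 1, m):
                    both = float(
                        2.0 * b[j, a] * Rxx[j, k] * b[k, t]
                        + 2.0 * b[k, a] * Rxx[k, j] * b[j, t]
                    )
                    pair = PathTerm(
                        PathType.CORR_CROSS_JK, j + 1, a + 1, both, k=k + 1, t=t + 1
                    )
                    out.append(_with_weight(pair, w * pair.value))
    return out


def generalized_decision(
    fit: StandardizedFit,
    j: int,
    *,
    level: float = config.ALPHA_CLASSIFY,
    rank: int = 0,
) -> DecisionResult:
    """Generalized decision coefficient R_y(j) of predictor j on the whole
    Y system.

    part_I collects the theta[alpha, alpha]-weighted same-response terms
    touching j (its squared direct terms plus the full doubled pair terms
    with every other predictor); part_II the theta[alpha, t]-weighted
    cross-response terms touching j.  Each unordered pair contributes its
    full doubled value to both of its members, so summing R_y(j) over j
    does not reproduce tr(B) — by construction, not by accident.
    """
    sys_ = fit.system
    m, p = sys_.m, sys_.p
    ji = _idx(j, m, "j")
    theta = fit.theta
    b = fit.b_star
    Rxx = sys_.Rxx
    components: list[PathTerm] = []

    part_I = 0.0
    for a in range(p):
        w = float(theta[a, a])
        direct = PathTerm(PathType.DIRECT_SAME, j, a + 1, float(b[ji, a] ** 2))
        components.append(_with_weight(direct, w * direct.value))
        part_I += w * direct.value
        for k in range(m):
            if k == ji:
                continue
            pair = PathTerm(
                PathType.CORR_SAME, j, a + 1,
                float(2.0 * b[ji, a] * Rxx[ji, k] * b[k, a]), k=k + 1,
            )
            components.append(_with_weight(pair, w * pair.value))
            part_I += w * pair.value

    part_II = 0.0
    for a in range(p):
        for t in range(a + 1, p):
            w = float(theta[a, t])
            direct = PathTerm(
                PathType.DIRECT_CROSS, j, a + 1,
                float(2.0 * b[ji, a] * b[ji, t]), t=t + 1,
            )
            components.append(_with_weight(direct, w * direct.value))
            part_II += w * direct.value
            for k in range(m):
                if k == ji:
                    continue
                jk = PathTerm(
                    PathType.CORR_CROSS_JK, j, a + 1,
                    float(2.0 * b[ji, a] * Rxx[ji, k] * b[k, t]), k=k + 1, t=t + 1,
                )
                kj = PathTerm(
                    PathType.CORR_CROSS_KJ, j, a + 1,
                    float(2.0 * b[k, a] * Rxx[k, ji] * b[ji, t]), k=k + 1, t=t + 1,
                )
                components.append(_with_weight(jk, w * jk.value))
                components.append(_with_weight(kj, w * kj.value))
                part_II += w * (jk.value + kj.value)

    value = part_I + part_II
    test = inference.generalized_decision_t_test(fit, j, value)
    return DecisionResult(
        scope="generalized",
        j=j,
        value=float(value),
        components=tuple(components),
        test=test,
        rank=rank,
        classification=_classify(value, test, level),
        part_I=float(part_I),
        part_II=float(part_II),
    )


def rank_decisions(
    fit: StandardizedFit, *, level: float = config.ALPHA_CLASSIFY
) -> list[DecisionResult]:
    """All m generalized decision coefficients, ranked by signed value.

    Rank 1 is the largest (most positive) coefficient; ties break by
    ascending predictor index.  Returned in rank order.
    """
    m = fit.system.m
    raw = [generalized_decision(fit, j, level=level) for j in range(1, m + 1)]
    ranks = _rank_descending([r.value for r in raw])
    ranked = [
        DecisionResult(
            scope=r.scope, j=r.j, value=r.value, components=r.components,
            test=r.test, rank=rank, classification=r.classification,
            alpha=r.alpha, part_I=r.part_I, part_II=r.part_II,
        )
        for r, rank in zip(raw, ranks)
    ]
    return sorted(ranked, key=lambda r: r.rank)


def _with_weight(term: PathTerm, weighted: float) -> PathTerm:
    return PathTerm(
        path_type=term.path_type, j=term.j, alpha=term.alpha, value=term.value,
        k=term.k, t=term.t, weighted_value=float(weighted),
    )


def _idx(idx: int, bound: int, what: str) -> int:
    idx = int(idx)
    if not 1 <= idx <= bound:
        raise IndexError(f"{what} = {idx} out of range 1..{bound}")
    return idx - 1
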