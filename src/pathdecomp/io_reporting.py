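"""Reading correlation/data tables, arrow-notation path strings, and
assembly of the full analysis report.

Reports mirror the field's standard table layouts: a correlation-division
table (direct / indirect / total effect per predictor and response), a
determination-division table with decision coefficients, the three
cross-response blocks, the weighted division summary, and the generalized
decision summary.  Numbers render to 4 decimal places in TSV; JSON keeps
full precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import config, inference, path_multi, path_one
from .model_core import CorrelationSystem, StandardizedFit, build_system
from .path_one import PathTerm, PathType

__all__ = [
    "load_correlation_csv",
    "write_correlation_csv",
    "load_data_csv",
    "render_path_string",
    "AnalysisReport",
    "build_report",
]

_ARROWS_ASCII = {"to": "->", "from": "<-", "corr": "<->"}
_ARROWS_UNICODE = {"to": "→", "from": "←", "corr": "↔"}


def load_correlation_csv(
    path: str | Path,
    n: int,
    names_x: Sequence[str],
    names_y: Sequence[str],
) -> CorrelationSystem:
    """Read a joint correlation matrix from CSV (header row + name column).

    Rows/columns are reordered to X block first according to ``names_x`` and
    ``names_y``, then validated by :func:`pathdecomp.model_core.build_system`.
    """
    frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    frame.index = frame.index.map(str)
    frame.columns = frame.columns.map(str)
    order = [str(v) for v in names_x] + [str(v) for v in names_y]
    missing = [v for v in order if v not in frame.columns or v not in frame.index]
    if missing:
        raise KeyError(f"variables absent from correlation file: {missing}")
    R = frame.loc[order, order].to_numpy(dtype=float)
    return build_system(R, n, names_x, names_y)


def write_correlation_csv(system: CorrelationSystem, path: str | Path) -> None:
    """Write the joint correlation matrix with a name header/column.

    Full float precision is preserved, so a read-back reproduces the
    identical system.
    """
    system.to_frame().to_csv(path, float_format="%.17g")


def load_data_csv(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a raw delimited data table (CSV or TSV, header row required)."""
    return pd.read_csv(path, sep=sep, engine="python")


def render_path_string(
    term: PathTerm,
    names_x: Sequence[str],
    names_y: Sequence[str],
    *,
    unicode_arrows: bool = False,
) -> str:
    """Arrow-notation label for one path term, e.g. ``y1<-x1<->x2->y2``.

    ASCII arrows by default so reports stay diff-able; pass
    ``unicode_arrows=True`` for the typeset form.
    """
    arrows = _ARROWS_UNICODE if unicode_arrows else _ARROWS_ASCII
    xj = names_x[term.j - 1]
    ya = names_y[term.alpha - 1]
    yt = names_y[term.t - 1] if term.t is not None else ya
    xk = names_x[term.k - 1] if term.k is not None else None
    if term.path_type in (PathType.DIRECT_SAME, PathType.DIRECT_CROSS):
        middle = xj
    elif term.path_type in (PathType.CORR_SAME, PathType.CORR_CROSS_JK):
        middle = f"{xj}{arrows['corr']}{xk}"
    else:  # CORR_CROSS_KJ: the k predictor is written first
        middle = f"{xk}{arrows['corr']}{xj}"
    return f"{ya}{arrows['from']}{middle}{arrows['to']}{yt}"


@dataclass
class AnalysisReport:
    """Every table of a complete analysis, plus collected warnings.

    ``tables`` maps section names to DataFrames; ``summary`` holds the
    scalar headline numbers.  Use :meth:`to_tsv` / :meth:`to_json` to
    serialize.
    """

    system: CorrelationSystem
    summary: dict[str, float]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "variables": {
                "x": list(self.system.names_x),
                "y": list(self.system.names_y),
                "n": self.system.n,
            },
            "summary": self.summary,
            "tables": {
                name: frame.to_dict(orient="records") for name, frame in self.tables.items()
            },
            "warnings": self.warnings,
        }
        return json.dumps(payload, indent=2, default=float)

    def to_tsv(self, section: str) -> str:
        frame = self.tables[section].copy()
        for col in frame.columns:
            if pd.api.types.is_float_dtype(frame[col]):
                frame[col] = frame[col].map(lambda v: f"{v:.4f}")
        return frame.to_csv(sep="\t", index=False)

    def sections(self) -> list[str]:
        return list(self.tables)


def _tests_table(fit: StandardizedFit) -> pd.DataFrame:
    sys_ = fit.system
    rows = []

    def add(res, **idx):
        rows.append(
            {
                "test": res.name,
                **idx,
                "statistic": res.statistic,
                "df": "/".join(f"{d:g}" for d in res.df),
                "p_value": res.p_value,
                "stars": res.stars,
                "status": res.status,
                **{k: v for k, v in res.extras.items()},
            }
        )

    add(inference.bartlett_independence_test(fit))
    for a in range(1, sys_.p + 1):
        add(inference.equation_f_test(fit, a), y=sys_.names_y[a - 1])
    for j in range(1, sys_.m + 1):
        for a in range(1, sys_.p + 1):
            add(
                inference.coefficient_t_test(fit, j, a),
                x=sys_.names_x[j - 1],
                y=sys_.names_y[a - 1],
            )
    for j in range(1, sys_.m + 1):
        add(inference.row_wilks_test(fit, j), x=sys_.names_x[j - 1])
    return pd.DataFrame(rows)


def _correlation_table(fit: StandardizedFit) -> pd.DataFrame:
    sys_ = fit.system
    rows = []
    for a in range(1, sys_.p + 1):
        for eff in path_one.decompose_correlation(fit, a):
            for ind in eff.indirects:
                rows.append(
                    {
                        "y": sys_.names_y[a - 1],
                        "x": sys_.names_x[eff.j - 1],
                        "direct_effect": eff.direct.value,
                        "path": render_path_string(ind, sys_.names_x, sys_.names_y),
                        "indirect_effect": ind.value,
                        "indirect_total": eff.indirect_total,
                        "total_effect": eff.total,
                        "residual_path": eff.residual_path,
                    }
                )
    return pd.DataFrame(rows)


def _determination_table(fit: StandardizedFit) -> pd.DataFrame:
    sys_ = fit.system
    rows = []
    for a in range(1, sys_.p + 1):
        decisions = {d.j: d for d in path_one.decision_coefficients(fit, a)}
        for j in range(1, sys_.m + 1):
            d = decisions[j]
            direct = next(
                c for c in d.components if c.path_type is PathType.DIRECT_SAME
            )
            for c in d.components:
                if c.path_type is PathType.DIRECT_SAME:
                    continue
                rows.append(
                    {
                        "y": sys_.names_y[a - 1],
                        "x": sys_.names_x[j - 1],
                        "direct_determination": direct.value,
                        "path": render_path_string(c, sys_.names_x, sys_.names_y),
                        "pair_determination": c.value,
                        "decision_coefficient": d.value,
                        "t": d.test.statistic,
                        "stars": d.test.stars,
                        "rank": d.rank,
                        "classification": d.classification,
                    }
                )
    return pd.DataFrame(rows)


def _cross_table(fit: StandardizedFit) -> pd.DataFrame:
    sys_ = fit.system
    rows = []
    for a in range(1, sys_.p + 1):
        for t in range(a + 1, sys_.p + 1):
            dec = path_multi.cross_correlation_decomposition(fit, a, t)
            for term in dec.terms:
                rows.append(
                    {
                        "y_pair": f"{sys_.names_y[a - 1]},{sys_.names_y[t - 1]}",
                        "path": render_path_string(term, sys_.names_x, sys_.names_y),
                        "path_type": term.path_type.value,
                        "value": term.value,
                        "x_mediated_correlation": dec.total,
                    }
                )
    return pd.DataFrame(rows)


def _division_table(fit: StandardizedFit) -> pd.DataFrame:
    sys_ = fit.system
    rows = []
    for term in path_multi.generalized_r2_division(fit):
        rows.append(
            {
                "path": render_path_string(term, sys_.names_x, sys_.names_y),
                "path_type": term.path_type.value,
                "value": term.value,
                "weighted_value": term.weighted_value,
            }
        )
    return pd.DataFrame(rows)


def _decision_table(fit: StandardizedFit, level: float) -> pd.DataFrame:
    sys_ = fit.system
    rows = []
    for d in path_multi.rank_decisions(fit, level=level):
        rows.append(
            {
                "x": sys_.names_x[d.j - 1],
                "generalized_decision": d.value,
                "part_I": d.part_I,
                "part_II": d.part_II,
                "t": d.test.statistic,
                "p_value": d.test.p_value,
                "stars": d.test.stars,
                "rank": d.rank,
                "classification": d.classification,
            }
        )
    return pd.DataFrame(rows)


def build_report(fit: StandardizedFit, *, level: float = config.ALPHA_CLASSIFY) -> AnalysisReport:
    """Assemble the full analysis report from one fit."""
    sys_ = fit.system
    summary = {
        "m": sys_.m,
        "p": sys_.p,
        "n": sys_.n,
        "v_xy": fit.v_xy,
        "R2_generalized": fit.R2_gen,
        "r_xy": fit.r_xy,
        "trB": fit.trB,
        "R2_exact_from_B": fit.R2_exact,
        "trB_gap": fit.trB_gap,
    }
    warnings_ = []
    if fit.trB_gap > config.TRB_GAP_WARN:
        warnings_.append(
            f"tr(B) overestimates the exact generalized determination "
            f"coefficient by {fit.trB_gap:.4f} (> {config.TRB_GAP_WARN}); the "
            f"trace-based division is a rough approximation here"
        )
    coef = pd.DataFrame(
        fit.b_star, index=list(sys_.names_x), columns=list(sys_.names_y)
    ).reset_index(names="x")
    report = AnalysisReport(system=sys_, summary=summary, warnings=warnings_)
    report.tables["coefficients"] = coef
    report.tables["tests"] = _tests_table(fit)
    report.tables["correlation_division"] = _correlation_table(fit)
    report.tables["determination_division"] = _determination_table(fit)
    report.tables["cross_division"] = _cross_table(fit)
    report.tables["generalized_division"] = _division_table(fit)
    report.tables["generalized_decisions"] = _decision_table(fit, level)
    return report
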