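"""Rank aggregation and reporting across the four ranking engines.

Four per-variable rank columns are produced:

* R1a — log-rank chi-square, larger = better rank;
* R1b — integral IS between the two Kaplan-Meier curves, larger = better;
* R2a — univariate Cox hazard ratio Exp(b), larger = better;
* R2b — multivariate Cox hazard ratio Exp(b), larger = better.

Ties break by the smaller p-value of the same engine, then lexicographic
variable name, so every rank column is a deterministic permutation of
1..K.  The final ranking defaults to the multivariate Cox order (method
``multivariate``); the selectable ``mean_is_multivariate`` method averages
the IS and multivariate ranks (ties resolved by the multivariate rank),
reflecting the view that IS measures the size of the survival separation
while the multivariate model measures a variable's behavior in the joint
system.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cox_ph import CoxFit
from .io_preprocess import Cohort, summarize
from .is_integral import ISResult, is_integral
from .kaplan_meier import (LogRankResult, StepSurvivalCurve, fit_km,
                           format_p, logrank_test)

__all__ = [
    "RankTable",
    "PipelineResult",
    "rank_by",
    "build_rank_table",
    "rank_table_from_stats",
    "final_ranking",
    "render_report",
    "run_pipeline",
    "run_pipeline_arrays",
]

_RANK_COLUMNS = ("r1a", "r1b", "r2a", "r2b", "final")


@dataclass(frozen=True)
class RankTable:
    """Per-variable statistics and the five rank columns (R1a, R1b, R2a,
    R2b, final); every rank column is a permutation of 1..K."""

    table: pd.DataFrame
    final_method: str = "multivariate"

    def __post_init__(self):
        k = len(self.table)
        for col in _RANK_COLUMNS:
            if col in self.table and sorted(self.table[col]) != list(range(1, k + 1)):
                raise ValueError(f"rank column {col!r} is not a permutation of 1..{k}")

    @property
    def variables(self) -> list[str]:
        return list(self.table.index)

    def ranks(self, column: str) -> dict[str, int]:
        return self.table[column].astype(int).to_dict()


def rank_by(values: Mapping[str, float], direction: str = "desc",
            tiebreak: Mapping[str, float] | None = None) -> dict[str, int]:
    """Dense 1-based ranks: sort by value (desc = largest first), break ties
    by the smaller tiebreak value (a p-value), then by name."""
    if len(values) < 2:
        raise ValueError("ranking needs at least 2 variables")
    if any(not np.isfinite(v) for v in values.values()):
        bad = [k for k, v in values.items() if not np.isfinite(v)]
        raise ValueError(f"non-finite ranking value(s) for {bad}")
    if direction not in ("desc", "asc"):
        raise ValueError(f"direction must be 'desc' or 'asc', got {direction!r}")
    sign = -1.0 if direction == "desc" else 1.0
    tb = dict(tiebreak or {})
    ordered = sorted(values, key=lambda k: (sign * values[k], tb.get(k, np.inf), k))
    return {name: i + 1 for i, name in enumerate(ordered)}


def _assemble(df: pd.DataFrame, final_method: str) -> RankTable:
    names = list(df.index)
    cols = {
        "r1a": rank_by(df["chi_square"].to_dict(), "desc", df["logrank_p"].to_dict()),
        "r1b": rank_by(df["is_months"].to_dict(), "desc", df["logrank_p"].to_dict()),
        "r2a": rank_by(df["uni_hr"].to_dict(), "desc", df["uni_p"].to_dict()),
        "r2b": rank_by(df["multi_hr"].to_dict(), "desc", df["multi_p"].to_dict()),
    }
    out = df.copy()
    for col, ranks in cols.items():
        out[col] = [ranks[n] for n in names]
    out["final"] = _final_column(out, final_method)
    return RankTable(out, final_method=final_method)


def _final_column(df: pd.DataFrame, method: str) -> list[int]:
    if method == "multivariate":
        return df["r2b"].astype(int).tolist()
    if method == "mean_is_multivariate":
        mean_rank = (df["r1b"] + df["r2b"]) / 2.0
        ranks = rank_by(mean_rank.to_dict(), "asc",
                        df["r2b"].astype(float).to_dict())
        return [ranks[n] for n in df.index]
    raise ValueError(f"unknown final-ranking method {method!r}")


def build_rank_table(km: Mapping[str, LogRankResult],
                     is_: Mapping[str, ISResult],
                     uni: Mapping[str, CoxFit],
                     multi: CoxFit,
                     final_method: str = "multivariate") -> RankTable:
    """Assemble the RankTable from the four engines' results.

    All four inputs must cover the same variable set; the multivariate fit
    contributes the coefficient of each variable from the joint model.
    """
    names = set(km)
    if not (names == set(is_) == set(uni) == set(multi.names)):
        raise ValueError(
            "variable-set mismatch across ranking inputs: "
            f"km={sorted(km)}, is={sorted(is_)}, uni={sorted(uni)}, "
            f"multi={sorted(multi.names)}"
        )
    rows = {}
    for name in sorted(names):
        u = uni[name].summary_row(name)
        m = multi.summary_row(name)
        rows[name] = {
            "chi_square": km[name].chi_square, "logrank_p": km[name].p_value,
            "is_months": is_[name].is_months,
            "uni_hr": u["exp_b"], "uni_p": u["p"],
            "uni_ci_lower": u["ci_lower"], "uni_ci_upper": u["ci_upper"],
            "multi_hr": m["exp_b"], "multi_p": m["p"],
            "multi_ci_lower": m["ci_lower"], "multi_ci_upper": m["ci_upper"],
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "variable"
    return _assemble(df, final_method)


def rank_table_from_stats(stats: pd.DataFrame,
                          final_method: str = "multivariate") -> RankTable:
    """RankTable from pre-computed per-variable statistics.

    ``stats`` needs columns chi_square, logrank_p, is_months, uni_hr, uni_p,
    multi_hr, multi_p (e.g. the printed statistics of a published study,
    when the patient-level data are unavailable)."""
    required = {"chi_square", "logrank_p", "is_months",
                "uni_hr", "uni_p", "multi_hr", "multi_p"}
    missing = required - set(stats.columns)
    if missing:
        raise ValueError(f"missing statistic column(s): {sorted(missing)}")
    return _assemble(stats.copy(), final_method)


def final_ranking(table: RankTable,
                  method: str | None = None) -> list[str]:
    """Variables ordered by final rank (best first)."""
    method = method or table.final_method
    df = table.table
    final = _final_column(df, method)
    order = sorted(zip(final, df.index))
    return [name for _, name in order]


@dataclass
class PipelineResult:
    """Everything the end-to-end ranking produced, per variable."""

    rank_table: RankTable
    curves: dict[str, tuple[StepSurvivalCurve, StepSurvivalCurve]]
    logrank: dict[str, LogRankResult]
    integrals: dict[str, ISResult]
    univariate: dict[str, CoxFit]
    multivariate: CoxFit
    counts: dict[str, tuple[int, float]]  # (n unfavorable, %)


def run_pipeline_arrays(times: np.ndarray, events: np.ndarray, X: np.ndarray,
                        names: Sequence[str], tmax: float | str = "auto",
                        ties: str = "breslow",
                        final_method: str = "multivariate") -> PipelineResult:
    """Array-level four-engine ranking (column j of X = binary factor j)."""
    from .cox_ph import fit_cox_arrays

    times = np.asarray(times, float)
    events = np.asarray(events, int)
    X = np.asarray(X, float)
    curves, lr, integrals, counts = {}, {}, {}, {}
    uni: dict[str, CoxFit] = {}
    for j, name in enumerate(names):
        mask = X[:, j] == 1
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise ValueError(f"factor {name!r}: each group needs >= 2 subjects")
        curve_M = fit_km(times[~mask], events[~mask])
        curve_m = fit_km(times[mask], events[mask])
        curves[name] = (curve_M, curve_m)
        lr[name] = logrank_test((times[~mask], events[~mask]),
                                (times[mask], events[mask]))
        integrals[name] = is_integral(curve_M, curve_m, tmax=tmax)
        counts[name] = summarize(times.size, X[:, j])
        uni[name] = fit_cox_arrays(times, events, X[:, [j]], names=[name],
                                   ties=ties)
    multi = fit_cox_arrays(times, events, X, names=list(names), ties=ties)
    table = build_rank_table(lr, integrals, uni, multi, final_method=final_method)
    return PipelineResult(table, curves, lr, integrals, uni, multi, counts)


def run_pipeline(cohort: Cohort, factors: Sequence[str],
                 tmax: float | str = "auto", ties: str = "breslow",
                 final_method: str = "multivariate") -> PipelineResult:
    """Run all four ranking engines on binary cohort factors and aggregate."""
    X = cohort.covariate_matrix(list(factors))
    return run_pipeline_arrays(cohort.times(), cohort.events(), X,
                               list(factors), tmax=tmax, ties=ties,
                               final_method=final_method)


def _fmt_hr(hr: float) -> str:
    # published convention: 2 decimals, 3 for ratios below 1
    return f"{hr:.3f}" if hr < 1 else f"{hr:.2f}"


def render_report(result_or_table: "PipelineResult | RankTable",
                  n_total: int | None = None) -> str:
    """Human-readable report: the KM/IS block, the Cox block, and the rank
    summary.  Deterministic: the same inputs render byte-identically."""
    if isinstance(result_or_table, PipelineResult):
        table = result_or_table.rank_table
        counts = result_or_table.counts
    else:
        table, counts = result_or_table, {}
    df = table.table
    lines = ["Prognostic-factor ranking report", "=" * 64, ""]

    lines.append("Kaplan-Meier / log-rank and integral IS")
    lines.append(f"{'variable':<28}{'N (%)':>14}{'chi2':>7}{'p':>8}"
                 f"{'R1a':>5}{'IS':>7}{'R1b':>5}")
    for name, row in df.sort_values("r1a").iterrows():
        npct = ""
        if counts.get(name):
            c, pct = counts[name]
            npct = f"{c} ({pct:.1f}%)"
        lines.append(
            f"{name:<28}{npct:>14}{row['chi_square']:>7.1f}"
            f"{format_p(row['logrank_p']):>8}{int(row['r1a']):>5}"
            f"{row['is_months']:>7.1f}{int(row['r1b']):>5}"
        )
    lines.append("")

    lines.append("Cox proportional hazards (univariate | multivariate)")
    lines.append(f"{'variable':<28}{'p':>8}{'HR':>7}{'95% CI':>12}{'R2a':>5}"
                 f"{'p':>8}{'HR':>7}{'95% CI':>12}{'R2b':>5}")
    has_ci = "uni_ci_lower" in df.columns
    for name, row in df.sort_values("r2a").iterrows():
        uci = (f"{row['uni_ci_lower']:.1f}-{row['uni_ci_upper']:.1f}"
               if has_ci else "")
        mci = (f"{row['multi_ci_lower']:.1f}-{row['multi_ci_upper']:.1f}"
               if has_ci else "")
        lines.append(
            f"{name:<28}{format_p(row['uni_p']):>8}{_fmt_hr(row['uni_hr']):>7}"
            f"{uci:>12}{int(row['r2a']):>5}"
            f"{format_p(row['multi_p']):>8}{_fmt_hr(row['multi_hr']):>7}"
            f"{mci:>12}{int(row['r2b']):>5}"
        )
    lines.append("")

    lines.append(f"Final ranking (method: {table.final_method})")
    for name in final_ranking(table):
        r = df.loc[name]
        lines.append(f"  {int(r['final']):>2}. {name}  "
                     f"(R1a {int(r['r1a'])}, R1b {int(r['r1b'])}, "
                     f"R2a {int(r['r2a'])}, R2b {int(r['r2b'])})")
    lines.append("")
    if n_total:
        lines.append(f"Cohort size: {n_total} subjects")
    return "\n".join(lines) + "\n"
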