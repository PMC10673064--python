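"""Kaplan-Meier product-limit estimation and the two-sample log-rank test.

Ranking engine #1: each binary prognostic factor splits the cohort in two,
the survival curves are estimated nonparametrically, and the factors are
ranked by the log-rank chi-square (larger chi-square = stronger separation
= better rank).

Conventions: S(t) is right-continuous (the value at an event time is the
post-jump value); when events and censorings share a time, events are
counted before the censored subjects leave the risk set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StepSurvivalCurve",
    "LogRankResult",
    "MedianSurvival",
    "fit_km",
    "survival_at",
    "median_survival",
    "logrank_test",
]


@dataclass(frozen=True)
class StepSurvivalCurve:
    """A right-continuous, non-increasing step estimate of S(t).

    ``times`` are the distinct event times; ``survival[i]`` is S(t) just
    after ``times[i]``.  ``max_time`` is the largest observed follow-up
    (event or censored) — the support of the estimate; evaluation past it
    carries the last value forward and is flagged as extrapolation.
    """

    times: np.ndarray        # strictly increasing distinct event times
    survival: np.ndarray     # S(t) after each event time
    n_at_risk: np.ndarray    # risk-set size just before each event time
    n_events: np.ndarray     # deaths at each event time (>= 1)
    n_censored: np.ndarray   # censorings in (previous event time, this one]
    n_total: int
    max_time: float

    def __post_init__(self):
        for name in ("times", "survival", "n_at_risk", "n_events", "n_censored"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if self.times.size:
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("event times must be strictly increasing")
            if np.any(np.diff(self.survival) > 1e-12):
                raise ValueError("survival must be non-increasing")
            if np.any(self.n_events < 1):
                raise ValueError("every listed time must carry >= 1 event")

    @property
    def last_value(self) -> float:
        return float(self.survival[-1]) if self.times.size else 1.0

    def greenwood_variance(self) -> np.ndarray:
        """Greenwood's cumulative variance terms Var[S(t)] / S(t)^2."""
        d, r = self.n_events.astype(float), self.n_at_risk.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(r > d, d / (r * (r - d)), np.inf)
        return np.cumsum(terms)


@dataclass(frozen=True)
class MedianSurvival:
    """Median survival with a Brookmeyer-Crowley confidence interval."""

    median: float
    ci_lower: float
    ci_upper: float
    ci_level: float
    defined: bool = True


@dataclass(frozen=True)
class LogRankResult:
    """Two-sample log-rank test: chi-square on 1 df."""

    chi_square: float
    p_value: float
    df: int = 1
    observed: np.ndarray = field(default=None)  # events per group
    expected: np.ndarray = field(default=None)  # hypergeometric expectation
    defined: bool = True


def _as_arrays(times: Sequence[float], events: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size != e.size:
        raise ValueError("times and events must have equal length")
    if t.size == 0:
        raise ValueError("empty input")
    if np.any(t < 0):
        raise ValueError("negative follow-up time")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event flags must be 0 or 1")
    return t, e


def fit_km(times: Sequence[float], events: Sequence[int]) -> StepSurvivalCurve:
    """Product-limit estimate S(t) = prod_{t_i <= t} (1 - d_i / r_i).

    d_i events and r_i at risk at each distinct event time t_i; censored
    times reduce the risk set after their time (events first on ties).
    """
    t, e = _as_arrays(times, events)
    n = t.size
    order = np.lexsort((1 - e, t))  # time asc, events before censorings
    t, e = t[order], e[order]

    event_times, d = np.unique(t[e == 1], return_counts=True)
    r = n - np.searchsorted(t, event_times, side="left")
    surv = np.cumprod(1.0 - d / r) if event_times.size else np.array([])

    # censored in (previous event time, current event time]
    cens_t = np.sort(t[e == 0])
    cum = np.searchsorted(cens_t, event_times, side="right")
    n_cens = np.diff(np.concatenate(([0], cum)))
    return StepSurvivalCurve(
        times=event_times, survival=surv, n_at_risk=r, n_events=d,
        n_censored=n_cens, n_total=n, max_time=float(t.max()),
    )


def survival_at(curve: StepSurvivalCurve, t: float | Sequence[float],
                return_flag: bool = False):
    """Right-continuous evaluation of the step curve; S(0) = 1.

    Past ``max_time`` the last value is carried forward; with
    ``return_flag=True`` a boolean marks such extrapolated evaluations.
    """
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("negative evaluation time")
    vals = np.concatenate(([1.0], curve.survival))
    idx = np.searchsorted(curve.times, tt, side="right")
    out = vals[idx]
    flag = tt > curve.max_time
    if np.isscalar(t) or tt.ndim == 0:
        out, flag = float(out), bool(flag)
    if return_flag:
        return out, flag
    return out


def median_survival(curve: StepSurvivalCurve, ci_level: float = 0.95) -> MedianSurvival:
    """Smallest t with S(t) <= 0.5, with a Brookmeyer-Crowley interval.

    The CI inverts the test |g(S(t)) - g(0.5)| / se <= z on the
    log(-log) scale with Greenwood variance; an unbracketed bound is
    reported as infinity, and a curve never crossing 0.5 yields a flagged,
    undefined median rather than an error.
    """
    if curve.n_total < 2:
        raise ValueError("median CI needs a curve from >= 2 subjects")
    below = np.flatnonzero(curve.survival <= 0.5)
    if below.size == 0:
        return MedianSurvival(np.nan, np.nan, np.nan, ci_level, defined=False)
    med = float(curve.times[below[0]])

    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    s = curve.survival
    gw = curve.greenwood_variance()
    g_target = np.log(-np.log(0.5))
    with np.errstate(divide="ignore", invalid="ignore"):
        interior = (s > 0) & (s < 1) & np.isfinite(gw)
        zstat = np.full(s.shape, np.inf)
        se_g = np.sqrt(gw[interior]) / np.abs(np.log(s[interior]))
        zstat[interior] = (np.log(-np.log(s[interior])) - g_target) / se_g
    inside = np.abs(zstat) <= z
    if not inside.any():
        return MedianSurvival(med, -np.inf, np.inf, ci_level)
    idx = np.flatnonzero(inside)
    lo = float(curve.times[idx[0]])
    # upper bound open if the curve still sits inside the band at its end
    hi = float(curve.times[idx[-1] + 1]) if idx[-1] + 1 < curve.times.size else np.inf
    return MedianSurvival(med, lo, hi, ci_level)


def logrank_test(group_a: tuple[Sequence[float], Sequence[int]],
                 group_b: tuple[Sequence[float], Sequence[int]]) -> LogRankResult:
    """Standard two-sample log-rank test.

    At each distinct event time the expected events per group come from the
    hypergeometric mean and the variance from the hypergeometric variance;
    chi_square = (sum(O - E))^2 / sum(V) on 1 df.  Zero events overall make
    the statistic undefined and yield a flagged result.
    """
    ta, ea = _as_arrays(*group_a)
    tb, eb = _as_arrays(*group_b)
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb])
    g = np.concatenate([np.zeros(ta.size, int), np.ones(tb.size, int)])

    if not np.any(e == 1):
        return LogRankResult(np.nan, np.nan, observed=np.zeros(2),
                             expected=np.zeros(2), defined=False)

    # distinct event times with events/at-risk per group, fully vectorized
    order = np.argsort(t, kind="stable")
    ts, es, gs = t[order], e[order], g[order]
    uniq, start = np.unique(ts, return_index=True)
    d_all = np.add.reduceat(es, start).astype(float)
    d_a = np.add.reduceat(es * (gs == 0), start).astype(float)
    r_all = (t.size - start).astype(float)
    ta_sorted = np.sort(ta)
    r_a = (ta.size - np.searchsorted(ta_sorted, uniq, side="left")).astype(float)

    mask = d_all > 0
    d_all, d_a, r_all, r_a = d_all[mask], d_a[mask], r_all[mask], r_a[mask]
    o_a = d_a.sum()
    e_a = float(np.sum(d_all * r_a / r_all))
    frac = r_a / r_all
    with np.errstate(invalid="ignore"):
        vterms = np.where(r_all > 1,
                          d_all * frac * (1 - frac) * (r_all - d_all) / (r_all - 1),
                          0.0)
    v = float(vterms.sum())
    obs = np.array([o_a, d_all.sum() - o_a])
    exp = np.array([e_a, obs.sum() - e_a])
    if v <= 0:
        # no between-group variability (e.g. one group exhausted immediately)
        chi2 = 0.0 if abs(o_a - e_a) < 1e-12 else np.nan
        defined = not np.isnan(chi2)
        p = 1.0 if defined else np.nan
        return LogRankResult(chi2, p, observed=obs, expected=exp, defined=defined)
    chi2 = (o_a - e_a) ** 2 / v
    p = float(stats.chi2.sf(chi2, df=1))
    return LogRankResult(float(chi2), p, observed=obs, expected=exp)


def format_p(p: float) -> str:
    """Clinical-table formatting: 3 decimals, '<0.001' below that."""
    if not np.isfinite(p):
        return "NA"
    return "<0.001" if p < 0.001 else f"{p:.3f}"
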