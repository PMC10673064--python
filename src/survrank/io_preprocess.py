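"""Cohort tables, binarization of prognostic markers, and cohort summaries.

A cohort is one row per subject: an identifier, overall-survival follow-up
time in months, an event indicator (1 = death observed, 0 = censored), and
named covariates.  Binary prognostic factors are coded 0 = favorable level,
1 = unfavorable level, so that positive Cox coefficients always mean worse
survival.  Continuous markers (C-reactive protein in mg/L, albumin in g/L,
metastasis size in cm, ...) are converted to binary factors either at a
laboratory reference cutpoint or at the sample median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SurvivalRecord",
    "BinaryFactor",
    "Cohort",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "write_life_table",
    "binarize_threshold",
    "binarize_median",
    "apply_factor",
    "parse_factor_config",
    "summarize",
    "round_half_away",
]

_RESERVED_COLUMNS = ("subject_id", "time_months", "event")


class CohortValidationError(ValueError):
    """Raised when a cohort table violates an invariant.

    Carries row-indexed diagnostics so the offending input line can be fixed.
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject: follow-up time (months), event flag, named covariates."""

    subject_id: str
    time: float
    event: int
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.time > 0) or not math.isfinite(self.time):
            raise ValueError(
                f"subject {self.subject_id!r}: time must be a positive finite "
                f"number of months, got {self.time!r}"
            )
        if self.event not in (0, 1):
            raise ValueError(
                f"subject {self.subject_id!r}: event must be 0 (censored) or "
                f"1 (death), got {self.event!r}"
            )


@dataclass(frozen=True)
class BinaryFactor:
    """A binarized prognostic variable: its cut rule and unfavorable side.

    ``rule`` is one of ``threshold_ge``, ``threshold_le``, ``median_ge``,
    ``median_le``; the ``_ge`` / ``_le`` suffix states which side of the
    cutpoint is coded 1 (unfavorable).
    """

    name: str
    rule: str
    cutpoint: float
    unfavorable_level: str = ""

    _RULES = ("threshold_ge", "threshold_le", "median_ge", "median_le")

    def __post_init__(self) -> None:
        if self.rule not in self._RULES:
            raise ValueError(f"unknown rule {self.rule!r}; expected one of {self._RULES}")
        if not math.isfinite(self.cutpoint):
            raise ValueError(f"factor {self.name!r}: cutpoint must be finite")

    @property
    def direction(self) -> str:
        return self.rule.rsplit("_", 1)[1]

    def describe(self) -> str:
        op = "≥" if self.direction == "ge" else "≤"
        return f"{self.name} {op} {self.cutpoint:g}"


@dataclass
class Cohort:
    """An ordered collection of :class:`SurvivalRecord` plus covariate metadata.

    ``variables`` maps covariate name -> free-form metadata (kind, unit, cut
    rule); ``metadata`` holds provenance such as the true simulation
    parameters of a synthetic cohort.
    """

    records: list[SurvivalRecord]
    variables: dict[str, dict] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError([f"duplicate subject_id(s): {dupes}"])

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n(self) -> int:
        return len(self.records)

    def times(self) -> np.ndarray:
        return np.array([r.time for r in self.records], dtype=float)

    def events(self) -> np.ndarray:
        return np.array([r.event for r in self.records], dtype=int)

    def covariate(self, name: str) -> np.ndarray:
        """Column of one covariate; missing values are an error, never imputed."""
        out = np.empty(len(self.records), dtype=float)
        for i, r in enumerate(self.records):
            if name not in r.covariates:
                raise CohortValidationError(
                    [f"row {i} (subject {r.subject_id!r}): covariate {name!r} missing"]
                )
            out[i] = r.covariates[name]
        return out

    def covariate_matrix(self, names: Sequence[str]) -> np.ndarray:
        return np.column_stack([self.covariate(n) for n in names]) if names else np.empty((self.n, 0))

    def to_frame(self) -> pd.DataFrame:
        covnames = sorted({k for r in self.records for k in r.covariates})
        rows = [
            {
                "subject_id": r.subject_id,
                "time_months": r.time,
                "event": r.event,
                **{c: r.covariates.get(c, np.nan) for c in covnames},
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=[*_RESERVED_COLUMNS, *covnames])

    def split(self, factor_name: str) -> tuple["Cohort", "Cohort"]:
        """Split into (favorable = coded 0, unfavorable = coded 1) subcohorts."""
        values = self.covariate(factor_name)
        fav = [r for r, v in zip(self.records, values) if v == 0]
        unf = [r for r, v in zip(self.records, values) if v == 1]
        if len(fav) < 2 or len(unf) < 2:
            raise CohortValidationError(
                [f"factor {factor_name!r}: each compared group needs >= 2 subjects "
                 f"(got {len(fav)} favorable, {len(unf)} unfavorable)"]
            )
        return Cohort(fav, dict(self.variables)), Cohort(unf, dict(self.variables))


def read_cohort(path: str | Path, schema: Mapping[str, str] | None = None,
                sep: str | None = None) -> Cohort:
    """Read a delimited cohort table (comma default, tab accepted).

    The header must name the subject id, follow-up time and event columns;
    ``schema`` remaps nonstandard column names, e.g.
    ``{"time_months": "os_months"}``.  Rows violating an invariant are
    rejected with row-indexed diagnostics.
    """
    schema = dict(schema or {})
    colmap = {std: schema.get(std, std) for std in _RESERVED_COLUMNS}
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise CohortValidationError([f"missing mandatory column(s): {missing}"])

    covcols = [c for c in df.columns if c not in set(colmap.values())]
    problems: list[str] = []
    records: list[SurvivalRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        sid = str(row[colmap["subject_id"]])
        time = pd.to_numeric(row[colmap["time_months"]], errors="coerce")
        event = pd.to_numeric(row[colmap["event"]], errors="coerce")
        if pd.isna(time) or not math.isfinite(time) or time <= 0:
            problems.append(f"row {i}: non-positive or non-numeric time "
                            f"{row[colmap['time_months']]!r}")
            continue
        if event not in (0, 1):
            problems.append(f"row {i}: event must be 0 or 1, got "
                            f"{row[colmap['event']]!r}")
            continue
        covs = {}
        for c in covcols:
            v = pd.to_numeric(row[c], errors="coerce")
            if pd.isna(v):
                problems.append(f"row {i}: covariate {c!r} is missing or non-numeric")
                break
            covs[c] = float(v)
        else:
            records.append(SurvivalRecord(sid, float(time), int(event), covs))
    if problems:
        raise CohortValidationError(problems)
    return Cohort(records, variables={c: {} for c in covcols})


def write_cohort(cohort: Cohort, path: str | Path, sep: str = ",") -> None:
    """Write a cohort table readable back by :func:`read_cohort`."""
    cohort.to_frame().to_csv(path, sep=sep, index=False)


def write_life_table(curve, path: str | Path, sep: str = ",") -> None:
    """Write a life table: time, n_at_risk, n_events, n_censored, survival."""
    pd.DataFrame(
        {
            "time": curve.times,
            "n_at_risk": curve.n_at_risk,
            "n_events": curve.n_events,
            "n_censored": curve.n_censored,
            "survival": curve.survival,
        }
    ).to_csv(path, sep=sep, index=False)


def _check_finite(values: np.ndarray) -> None:
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        raise ValueError(f"non-finite value(s) at index {bad.tolist()}")


def binarize_threshold(values: Iterable[float], cutpoint: float,
                       direction: str = "ge") -> np.ndarray:
    """0/1 assignment at a fixed cutpoint.

    ``ge``: 1 iff value >= cutpoint (elevated marker unfavorable, e.g.
    CRP >= 6 mg/L); ``le``: 1 iff value <= cutpoint (low marker unfavorable,
    e.g. albumin <= 38 g/L).
    """
    arr = np.asarray(list(values), dtype=float)
    _check_finite(arr)
    if not math.isfinite(cutpoint):
        raise ValueError("cutpoint must be finite")
    if direction == "ge":
        return (arr >= cutpoint).astype(int)
    if direction == "le":
        return (arr <= cutpoint).astype(int)
    raise ValueError(f"direction must be 'ge' or 'le', got {direction!r}")


def binarize_median(values: Iterable[float], direction: str = "ge",
                    name: str = "") -> tuple[BinaryFactor, np.ndarray]:
    """Binarize at the sample median (markers without a reference range).

    Even n: the median is the mean of the two central order statistics.
    Values equal to the cutpoint take the ">=" side.  All-identical values
    are rejected: the split would leave one group empty.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("median binarization needs at least 2 values")
    _check_finite(arr)
    if np.all(arr == arr[0]):
        raise ValueError("all values identical: median split is degenerate")
    cut = float(np.median(arr))
    factor = BinaryFactor(
        name=name or "median_factor",
        rule=f"median_{direction}",
        cutpoint=cut,
        unfavorable_level=f"{'>=' if direction == 'ge' else '<='} {cut:g}",
    )
    return factor, binarize_threshold(arr, cut, direction)


def apply_factor(cohort: Cohort, source: str, factor: BinaryFactor) -> np.ndarray:
    """Assignment of ``factor`` applied to continuous covariate ``source``."""
    return binarize_threshold(cohort.covariate(source), factor.cutpoint, factor.direction)


def parse_factor_config(path: str | Path) -> dict[str, dict]:
    """Read the factor-definition config (YAML-style key-value text).

    Each entry: ``name: {rule: threshold_ge|threshold_le|median_ge|median_le,
    cutpoint: <number, omitted for median rules>}``.  Already-binary columns
    may be declared with ``rule: binary``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    for name, entry in cfg.items():
        if not isinstance(entry, dict) or "rule" not in entry:
            raise ValueError(f"factor {name!r}: config entry must declare a rule")
        if entry["rule"].startswith("threshold") and "cutpoint" not in entry:
            raise ValueError(f"factor {name!r}: threshold rule needs a cutpoint")
    return cfg


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (65.45 -> 65.5), unlike banker's rounding."""
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def summarize(cohort_or_n: Cohort | int, assignment: Iterable[float]) -> tuple[int, float]:
    """(count unfavorable, percentage) for a factor assignment.

    Percentage = 100 * count / n, rounded half-away-from-zero to 1 decimal,
    the convention matching a clinical "N (%)" table column.
    """
    n = cohort_or_n.n if isinstance(cohort_or_n, Cohort) else int(cohort_or_n)
    if n <= 0:
        raise ValueError("empty cohort")
    arr = np.asarray(list(assignment), dtype=float)
    if arr.size != n:
        raise ValueError(f"assignment length {arr.size} != cohort size {n}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("assignment must be 0/1")
    count = int(arr.sum())
    return count, round_half_away(100.0 * count / n, 1)
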