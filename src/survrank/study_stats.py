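"""Published per-variable statistics of the motivating clinical cohort.

The source study (371 curative-intent liver resections for colorectal liver
metastases, single center, 2000-2020) reports for each of nine binary
prognostic factors: the unfavorable-level count, the log-rank chi-square and
p-value, the integral IS between the two Kaplan-Meier curves (months), and
the univariate and multivariate Cox hazard ratios with Wald p-values and
95% CIs.  The patient-level data are confidential, so these printed
summary statistics are the reference input for rank-reconstruction: feeding
them through the ranking operations must reproduce the published rank
columns and the final ranking 1-9.

p-values printed as "<0.001" are stored as 0.0005 (only their order matters,
for tie-breaking); ``format_p`` restores the printed form.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["STUDY_STATS", "PUBLISHED_RANKS", "COHORT_N", "study_stats_frame"]

COHORT_N = 371
MEDIAN_OS_MONTHS = 40.0
MEDIAN_OS_CI = (36.4, 43.6)
N_MALE = 243

_LT = 0.0005  # stands for a printed "<0.001"

# name: (count, chi_square, logrank_p, is_months,
#        uni_p, uni_hr, uni_lo, uni_hi, multi_p, multi_hr, multi_lo, multi_hi)
STUDY_STATS: dict[str, dict] = {
    "positive_resection_margin": dict(
        count=44, chi_square=20.0, logrank_p=_LT, is_months=28.1,
        uni_p=_LT, uni_hr=2.04, uni_ci=(1.5, 2.8),
        multi_p=_LT, multi_hr=1.79, multi_ci=(1.3, 2.5)),
    "infiltrated_lymph_nodes": dict(
        count=233, chi_square=21.6, logrank_p=_LT, is_months=26.6,
        uni_p=_LT, uni_hr=1.65, uni_ci=(1.3, 2.0),
        multi_p=_LT, multi_hr=1.55, multi_ci=(1.2, 1.9)),
    "crp_elevated": dict(
        count=164, chi_square=16.5, logrank_p=_LT, is_months=20.6,
        uni_p=_LT, uni_hr=1.53, uni_ci=(1.2, 1.9),
        multi_p=0.012, multi_hr=1.35, multi_ci=(1.1, 1.7)),
    "asa_2_3": dict(
        count=213, chi_square=8.4, logrank_p=0.004, is_months=16.6,
        uni_p=0.004, uni_hr=1.35, uni_ci=(1.1, 1.7),
        multi_p=0.009, multi_hr=1.33, multi_ci=(1.1, 1.6)),
    "albumin_low": dict(
        count=131, chi_square=6.7, logrank_p=0.010, is_months=14.7,
        uni_p=0.011, uni_hr=1.33, uni_ci=(1.1, 1.6),
        multi_p=0.270, multi_hr=1.14, multi_ci=(0.9, 1.4)),
    "multiple_metastases": dict(
        count=203, chi_square=5.1, logrank_p=0.024, is_months=12.3,
        uni_p=0.026, uni_hr=1.26, uni_ci=(1.0, 1.6),
        multi_p=0.087, multi_hr=1.21, multi_ci=(1.0, 1.5)),
    "large_metastasis": dict(
        count=187, chi_square=4.8, logrank_p=0.028, is_months=11.1,
        uni_p=0.030, uni_hr=1.25, uni_ci=(1.0, 1.5),
        multi_p=0.217, multi_hr=1.14, multi_ci=(0.9, 1.4)),
    "right_sided_primary": dict(
        count=76, chi_square=4.2, logrank_p=0.040, is_months=13.3,
        uni_p=0.042, uni_hr=1.30, uni_ci=(1.0, 1.7),
        multi_p=0.137, multi_hr=1.24, multi_ci=(0.9, 1.6)),
    "fibrinogen_elevated": dict(
        count=218, chi_square=0.5, logrank_p=0.467, is_months=3.2,
        uni_p=0.471, uni_hr=1.080, uni_ci=(0.9, 1.3),
        multi_p=0.872, multi_hr=0.982, multi_ci=(0.8, 1.2)),
}

# The published rank columns: R1a (log-rank chi-square), R1b (integral IS),
# R2a (univariate HR), R2b (multivariate HR), and the final ranking.
PUBLISHED_RANKS: dict[str, dict[str, int]] = {
    "infiltrated_lymph_nodes":   dict(r1a=1, r1b=2, r2a=2, r2b=2, final=2),
    "positive_resection_margin": dict(r1a=2, r1b=1, r2a=1, r2b=1, final=1),
    "crp_elevated":              dict(r1a=3, r1b=3, r2a=3, r2b=3, final=3),
    "asa_2_3":                   dict(r1a=4, r1b=4, r2a=4, r2b=4, final=4),
    "albumin_low":               dict(r1a=5, r1b=5, r2a=5, r2b=8, final=8),
    "multiple_metastases":       dict(r1a=6, r1b=7, r2a=7, r2b=6, final=6),
    "large_metastasis":          dict(r1a=7, r1b=8, r2a=8, r2b=7, final=7),
    "right_sided_primary":       dict(r1a=8, r1b=6, r2a=6, r2b=5, final=5),
    "fibrinogen_elevated":       dict(r1a=9, r1b=9, r2a=9, r2b=9, final=9),
}


def study_stats_frame() -> pd.DataFrame:
    """The reference statistics as a tidy DataFrame (one row per factor)."""
    rows = []
    for name, s in STUDY_STATS.items():
        rows.append({
            "variable": name, "count": s["count"], "n": COHORT_N,
            "chi_square": s["chi_square"], "logrank_p": s["logrank_p"],
            "is_months": s["is_months"],
            "uni_p": s["uni_p"], "uni_hr": s["uni_hr"],
            "uni_ci_lower": s["uni_ci"][0], "uni_ci_upper": s["uni_ci"][1],
            "multi_p": s["multi_p"], "multi_hr": s["multi_hr"],
            "multi_ci_lower": s["multi_ci"][0], "multi_ci_upper": s["multi_ci"][1],
        })
    return pd.DataFrame(rows).set_index("variable")
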