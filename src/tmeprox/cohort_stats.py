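"""Cohort-level statistics linking spatial metrics to clinical response.

Group comparisons use the two-sided Mann-Whitney U test (exact enumeration
for small tie-free samples, normal approximation with tie and continuity
corrections otherwise); categorical PD-L1 calls use the chi-square test;
quartile stratification summarizes responder fractions per density
quartile; and the density-adjusted proximity comparison asks whether the
proximity metric carries responder signal beyond the two marginal
densities, via rank residualization (proximity ranks regressed on the two
density ranks, residuals compared between groups).  No multiple-testing
correction is applied by default; a Benjamini-Hochberg helper is provided.

p-values are unadjusted two-sided throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: largest pooled sample for which the exact Mann-Whitney null is enumerated
EXACT_MW_MAX_N = 16


@dataclass(frozen=True)
class StatResult:
    test: str
    statistic: float
    p_value: float
    summaries: dict = field(default_factory=dict)
    note: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _group_summary(values: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "n": int(len(values)),
        "median": float(med),
        "min": float(values.min()),
        "max": float(values.max()),
        "iqr": (float(q1), float(q3)),
    }


def mann_whitney(group_a, group_b) -> StatResult:
    """Two-sided Mann-Whitney U comparison of two samples.

    The exact null distribution is enumerated when the pooled sample has at
    most :data:`EXACT_MW_MAX_N` observations and no ties; otherwise the
    normal approximation with tie correction and continuity correction is
    used.  Group medians and ranges are reported alongside U and p.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= EXACT_MW_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return StatResult(
        test="mann-whitney",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        summaries={"a": _group_summary(a), "b": _group_summary(b)},
        note=f"method={method}",
    )


def chi_square(contingency, yates: bool = False) -> StatResult:
    """Pearson chi-square test on an r x k contingency table of counts,
    with optional Yates continuity correction for 2x2 tables."""
    table = np.asarray(contingency, float)
    if table.ndim != 2 or np.any(table < 0):
        raise ValueError("contingency must be a 2-D nonnegative count table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate table: a row or column sums to zero")
    res = stats.chi2_contingency(table, correction=yates)
    return StatResult(
        test="chi-square",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        summaries={"dof": int(res.dof)},
        note="yates" if yates else "",
    )


@dataclass(frozen=True)
class QuartileSummary:
    metric: str
    assignments: pd.DataFrame  # specimen_id, value, quartile (1..4), responder
    responder_fraction: dict  # quartile -> fraction

    def fraction(self, quartile: int) -> float:
        return self.responder_fraction[quartile]


def quartile_stratify(
    records: pd.DataFrame,
    metric: str,
    responder_col: str = "responder",
    id_col: str = "specimen_id",
) -> QuartileSummary:
    """Split the cohort into quartiles of ``metric`` and report the
    responder fraction in each.

    Quartiles are rank-based: quartile = ceil(4 * rank / n) with competition
    (minimum) ranks, so tied specimens fall in the lower quartile; quartile
    sizes differ by at most one in the absence of ties.
    """
    df = records.loc[records[metric].notna(), [id_col, metric, responder_col]].copy()
    n = len(df)
    if n < 4:
        raise ValueError(f"need >= 4 non-missing values for quartiles, got {n}")
    ranks = stats.rankdata(df[metric].to_numpy(float), method="min")
    quartile = np.ceil(4.0 * ranks / n).astype(int)
    quartile = np.clip(quartile, 1, 4)
    df["quartile"] = quartile
    frac = {
        int(q): float(df.loc[df["quartile"] == q, responder_col].mean())
        for q in sorted(df["quartile"].unique())
    }
    return QuartileSummary(metric, df.reset_index(drop=True), frac)


def density_adjusted_proximity(
    records: pd.DataFrame,
    proximity_col: str = "pd1_near_pdl1_density",
    density_cols: tuple = ("pd1_density_total", "pdl1_density_total"),
    responder_col: str = "responder",
) -> StatResult:
    """Does the proximity metric separate responders beyond the marginal
    PD-1+ and PD-L1+ densities?

    Rank residualization: the proximity-density ranks are regressed (least
    squares, with intercept) on the ranks of the two marginal densities;
    the residuals are compared between responders and non-responders with
    the Mann-Whitney test.  This is one defensible reading of "controlling
    for density" and is labeled as such in the result note.
    """
    cols = [proximity_col, *density_cols, responder_col]
    df = records.dropna(subset=cols)
    if len(df) < 6:
        raise ValueError("density adjustment is unstable below n = 6")
    y = stats.rankdata(df[proximity_col].to_numpy(float))
    design = np.column_stack(
        [np.ones(len(df))]
        + [stats.rankdata(df[c].to_numpy(float)) for c in density_cols]
    )
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    # an exact fit leaves pure floating-point noise, which is not exchangeable;
    # snap it to zero so perfect mediation yields a null result
    resid[np.abs(resid) < 1e-8 * len(df)] = 0.0
    grp = df[responder_col].to_numpy(bool)
    if not grp.any() or grp.all():
        raise ValueError("both responder groups must be represented")
    if np.ptp(resid) == 0.0:
        base = StatResult(
            "mann-whitney", float(grp.sum() * (~grp).sum()) / 2.0, 1.0,
            note="degenerate: residuals identically zero",
        )
    else:
        base = mann_whitney(resid[grp], resid[~grp])
    return StatResult(
        test="density-adjusted proximity (rank residualization)",
        statistic=base.statistic,
        p_value=base.p_value,
        summaries=base.summaries,
        note="adjustment = least-squares residual of proximity ranks on "
        "marginal density ranks; one interpretation of 'controlled for density'",
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (off by default in every pipeline output; the
    cohort comparisons are reported unadjusted)."""
    p = np.asarray(p_values, float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out
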