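"""Group comparisons, brain-behavior correlations, FDR control, and cohort
descriptives over per-region summary tables.

Region tables are long DataFrames with columns (subject_id, region,
<metric columns>); subject records carry subject_id, group, age, education,
sex, and score columns. Group tests default to Welch's unequal-variance
t-test; `equal_var=True` restores the pooled test.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "group_ttest",
    "pearson_with_behavior",
    "partial_pearson",
    "bh_fdr",
    "add_fdr",
    "summarize_cohort",
    "round_half_up",
    "METRIC_FAMILIES",
]

# Metric families sharing an FDR correction (regions pooled within a family).
METRIC_FAMILIES: dict[str, list[str]] = {
    "tsa": ["mean_pos_lag", "mean_neg_lag", "pct_lag", "pct_lead"],
    "icc": ["pct_high_icc", "pct_low_icc"],
    "conjunction": [
        "pct_coupling_lowFC",
        "pct_coupling_highFC",
        "pct_uncoupling_lowFC",
        "pct_uncoupling_highFC",
    ],
}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (so 48.65 -> 48.7), as in descriptive tables."""
    factor = 10 ** ndigits
    return math.floor(x * factor + 0.5) / factor


def group_ttest(
    region_tables: pd.DataFrame,
    records: pd.DataFrame,
    metric: str,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Two-sample t-test (patient vs control) per region on one metric.

    Returns one row per region with the t statistic, degrees of freedom,
    two-sided p, per-group n, and a direction flag (sign of patient minus
    control mean). Regions where either group has < 2 non-missing values
    get a row with missing statistics.
    """
    merged = region_tables.merge(records[["subject_id", "group"]], on="subject_id")
    rows = []
    for region, sub in merged.groupby("region", sort=True):
        a = sub.loc[sub["group"] == "patient", metric].dropna().to_numpy(float)
        b = sub.loc[sub["group"] == "control", metric].dropna().to_numpy(float)
        row = {"region": region, "metric": metric,
               "n_patient": a.size, "n_control": b.size}
        if a.size < 2 or b.size < 2:
            row.update({"estimate": np.nan, "df": np.nan,
                        "p_uncorrected": np.nan, "direction": ""})
        else:
            res = sps.ttest_ind(a, b, equal_var=equal_var)
            row.update({
                "estimate": float(res.statistic),
                "df": float(res.df),
                "p_uncorrected": float(res.pvalue),
                "direction": "patient>control" if a.mean() > b.mean()
                else "patient<control" if a.mean() < b.mean() else "equal",
            })
        rows.append(row)
    return pd.DataFrame(rows)


def _pearson_row(x: np.ndarray, y: np.ndarray):
    if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        return np.nan, np.nan, "zero-variance"
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), ""


def pearson_with_behavior(
    region_tables: pd.DataFrame,
    records: pd.DataFrame,
    metric: str,
    score: str,
    group: str | None = None,
) -> pd.DataFrame:
    """Zero-order Pearson correlation, per region, between a regional metric
    and a behavioral score (optionally within one group only)."""
    rec = records if group is None else records[records["group"] == group]
    merged = region_tables.merge(rec[["subject_id", score]], on="subject_id")
    rows = []
    for region, sub in merged.groupby("region", sort=True):
        pair = sub[[metric, score]].dropna()
        row = {"region": region, "metric": metric, "score": score, "n": len(pair)}
        if len(pair) < 4:
            row.update({"estimate": np.nan, "p_uncorrected": np.nan,
                        "reason": "n<4"})
        else:
            r, p, reason = _pearson_row(pair[metric].to_numpy(float),
                                        pair[score].to_numpy(float))
            row.update({"estimate": r, "p_uncorrected": p, "reason": reason})
        rows.append(row)
    return pd.DataFrame(rows)


def partial_pearson(
    region_tables: pd.DataFrame,
    records: pd.DataFrame,
    metric: str,
    score: str,
    covariate: str = "age",
    group: str | None = None,
) -> pd.DataFrame:
    """First-order partial correlation of metric and score given a covariate.

    Both variables are residualized on the covariate (with intercept); the
    Pearson r of the residuals is the partial correlation, tested with
    t = r * sqrt((n-3)/(1-r^2)) on n-3 degrees of freedom.
    """
    rec = records if group is None else records[records["group"] == group]
    merged = region_tables.merge(rec[["subject_id", score, covariate]], on="subject_id")
    rows = []
    for region, sub in merged.groupby("region", sort=True):
        trip = sub[[metric, score, covariate]].dropna()
        n = len(trip)
        row = {"region": region, "metric": metric, "score": score,
               "covariate": covariate, "n": n}
        if n < 5:
            row.update({"estimate": np.nan, "p_uncorrected": np.nan, "reason": "n<5"})
            rows.append(row)
            continue
        z = trip[covariate].to_numpy(float)
        X = np.column_stack([np.ones(n), z])
        resid = {}
        degenerate = False
        for name in (metric, score):
            v = trip[name].to_numpy(float)
            beta, *_ = np.linalg.lstsq(X, v, rcond=None)
            resid[name] = v - X @ beta
            if resid[name].std(ddof=0) < 1e-12 * max(1.0, np.abs(v).max()):
                degenerate = True
        if degenerate:
            row.update({"estimate": np.nan, "p_uncorrected": np.nan,
                        "reason": "zero-variance"})
            rows.append(row)
            continue
        r = float(np.corrcoef(resid[metric], resid[score])[0, 1])
        df = n - 3
        t = r * math.sqrt(df / max(1e-300, 1.0 - r * r))
        p = 2.0 * sps.t.sf(abs(t), df)
        row.update({"estimate": r, "p_uncorrected": float(p), "reason": ""})
        rows.append(row)
    return pd.DataFrame(rows)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, clipped at 1. NaN entries are passed
    through and excluded from m.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    qv = np.empty(m)
    qv[order] = q
    out[ok] = qv
    return out


def add_fdr(stat_table: pd.DataFrame, alpha_uncorrected: float = 0.001,
            alpha_fdr: float = 0.01) -> pd.DataFrame:
    """Append q_fdr and a significance flag (p < alpha AND q < alpha_fdr)."""
    out = stat_table.copy()
    out["q_fdr"] = bh_fdr(out["p_uncorrected"].to_numpy())
    out["significant"] = (out["p_uncorrected"] < alpha_uncorrected) & (
        out["q_fdr"] < alpha_fdr
    )
    return out


def summarize_cohort(
    records: pd.DataFrame,
    cutoffs: dict[str, float] | None = None,
    group: str | None = None,
) -> pd.DataFrame:
    """Descriptive table: n/mean/SD/range per numeric variable, level counts
    and percentages for `sex`, and strictly-above-cutoff counts/percentages
    for each configured score cutoff. Percentages use half-up 1-decimal
    rounding."""
    if records.empty:
        raise ValueError("records table is empty")
    rec = records if group is None else records[records["group"] == group]
    skip = {"subject_id", "group", "sex"}
    rows = []
    for col in rec.columns:
        if col in skip or not pd.api.types.is_numeric_dtype(rec[col]):
            continue
        v = rec[col].dropna().to_numpy(float)
        rows.append({
            "variable": col, "n": v.size,
            "mean": v.mean() if v.size else np.nan,
            "sd": v.std(ddof=1) if v.size > 1 else np.nan,
            "min": v.min() if v.size else np.nan,
            "max": v.max() if v.size else np.nan,
            "count": np.nan, "pct": np.nan,
        })
    if "sex" in rec.columns:
        sex = rec["sex"].dropna()
        for level, count in sex.value_counts().sort_index().items():
            rows.append({
                "variable": f"sex={level}", "n": sex.size,
                "mean": np.nan, "sd": np.nan, "min": np.nan, "max": np.nan,
                "count": int(count),
                "pct": round_half_up(100.0 * count / sex.size),
            })
    for score, cutoff in (cutoffs or {}).items():
        v = rec[score].dropna().to_numpy(float)
        count = int((v > cutoff).sum())
        rows.append({
            "variable": f"{score}>{cutoff:g}", "n": v.size,
            "mean": np.nan, "sd": np.nan, "min": np.nan, "max": np.nan,
            "count": count,
            "pct": round_half_up(100.0 * count / v.size) if v.size else np.nan,
        })
    return pd.DataFrame(rows)
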