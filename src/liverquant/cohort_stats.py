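"""Longitudinal cohort statistics for the regeneration study.

Covers the statistical surface of the study: per-cell group summaries
(mean +/- SD with the censored cells left absent), integer percent changes of
group means against the pre-operative baseline, two-way fixed-effects ANOVA
(group x day) with Bonferroni-adjusted pairwise group contrasts per day,
Pearson correlation of each MR parameter against the regenerating relative
liver volume, and binomial logistic regression of fatal liver failure on the
MR parameters with a likelihood-ratio omnibus test and Nagelkerke pseudo-R2.

The ANOVA runs on the available cells of an unbalanced, censored design:
main effects are tested by Type-II model comparison (group adjusted for day
and vice versa) and the interaction against the additive model, with
rank-based degrees of freedom so empty cells (the liver-failure animals die
before day 5) are handled without imputation.  The Bonferroni family for the
post-tests is the full set of per-day pairwise group contrasts computed for
one parameter.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "StatResult",
    "group_summary",
    "summary_wide",
    "percent_change",
    "two_way_anova_bonferroni",
    "pearson_volume_correlation",
    "plf_logistic_regression",
    "nagelkerke_r2",
    "reproduce_abstract_changes",
    "ABSTRACT_CHANGES_FIXTURE",
]

MR_PARAMETERS = ("T1", "T2", "ADC", "MTR")
ABSTRACT_CHANGES_FIXTURE = "abstract_changes.json"


@dataclass
class StatResult:
    """One test outcome: statistic, raw and Bonferroni-adjusted p, extras."""

    test: str
    label: str
    statistic: float
    p_raw: float
    p_adjusted: Optional[float] = None
    extras: dict = field(default_factory=dict)


def group_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per (group, day, parameter) n, mean and SD (n-1 denominator).

    Cells absent from the table stay absent (censoring is preserved, never
    zero-filled).  Single-animal cells get sd = 0 with ``sd_defined=False``.
    """
    if table.empty:
        raise ValueError("empty cohort table")
    g = table.groupby(["group", "day", "parameter"], sort=True)["value"]
    out = g.agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1)).reset_index()
    out["sd_defined"] = out["n"] > 1
    out.loc[~out["sd_defined"], "sd"] = 0.0
    return out


def summary_wide(summary: pd.DataFrame, parameter: str, days=(0, 1, 2, 3, 5, 7)) -> pd.DataFrame:
    """Render one parameter as a day x group table of "mean+/-sd" strings with n/a."""
    sub = summary[summary["parameter"] == parameter]
    groups = sorted(sub["group"].unique())
    rows = []
    for day in days:
        row = {"day": day}
        for grp in groups:
            cell = sub[(sub["day"] == day) & (sub["group"] == grp)]
            row[grp] = (
                f"{cell['mean'].iloc[0]:.1f}±{cell['sd'].iloc[0]:.1f}" if len(cell) else "n/a"
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def percent_change(baseline: float, value: float, direction: str = "increase") -> int:
    """Integer percent change of ``value`` against ``baseline``, half-up rounded.

    ``direction='increase'`` reports ``100 (value - baseline) / baseline``;
    ``'decrease'`` reports the negated quantity, so a drop prints as a
    positive percentage (the convention of the study's Results text).
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    pct = 100.0 * (value - baseline) / baseline
    if direction == "decrease":
        pct = -pct
    elif direction != "increase":
        raise ValueError("direction must be 'increase' or 'decrease'")
    return _round_half_up(pct)


# ---------------------------------------------------------------------------
# Two-way ANOVA with Bonferroni post-tests
# ---------------------------------------------------------------------------

def _model_comparison_f(df: pd.DataFrame, full_formula: str, reduced_formula: str):
    """F test comparing nested OLS fits, with rank-based df (pinv fits)."""
    full = smf.ols(full_formula, data=df).fit()
    red = smf.ols(reduced_formula, data=df).fit()
    df_num = full.df_model - red.df_model
    df_den = full.df_resid
    if df_num <= 0 or df_den <= 0 or full.ssr <= 0:
        return np.nan, np.nan, df_num, df_den, full
    f = ((red.ssr - full.ssr) / df_num) / (full.ssr / df_den)
    p = float(stats.f.sf(f, df_num, df_den))
    return float(f), p, df_num, df_den, full


def two_way_anova_bonferroni(table: pd.DataFrame, parameter: str) -> List[StatResult]:
    """Group x day fixed-effects ANOVA plus per-day pairwise Bonferroni tests.

    Returns the omnibus effects (group, day, interaction) followed by every
    per-day pairwise group contrast; each contrast's t statistic uses the
    pooled residual mean square of the full interaction model, and its p is
    Bonferroni-scaled by the total number of contrasts computed for this
    parameter (capped at 1).  Groups with fewer than two animals at every day
    are excluded with a warning.
    """
    df = table[table["parameter"] == parameter][["animal_id", "group", "day", "value"]].copy()
    if df.empty:
        raise ValueError(f"no records for parameter {parameter!r}")
    keep = []
    for grp, sub in df.groupby("group"):
        if (sub.groupby("day")["value"].count() >= 2).any():
            keep.append(grp)
        else:
            warnings.warn(f"group {grp!r} has <2 animals at every day; excluded from ANOVA")
    df = df[df["group"].isin(keep)]
    if df["group"].nunique() < 2 or df["day"].nunique() < 2:
        raise ValueError("need at least two groups and two days with data")

    results: List[StatResult] = []
    f, p, dfn, dfd, full = _model_comparison_f(
        df, "value ~ C(group) * C(day)", "value ~ C(group) + C(day)"
    )
    fg, pg, dfng, dfdg, _ = _model_comparison_f(df, "value ~ C(group) + C(day)", "value ~ C(day)")
    fd, pd_, dfnd, dfdd, _ = _model_comparison_f(df, "value ~ C(group) + C(day)", "value ~ C(group)")
    results.append(StatResult("anova", "group", fg, pg, extras={"df": (dfng, dfdg), "parameter": parameter}))
    results.append(StatResult("anova", "day", fd, pd_, extras={"df": (dfnd, dfdd), "parameter": parameter}))
    results.append(StatResult("anova", "group:day", f, p, extras={"df": (dfn, dfd), "parameter": parameter}))

    mse = full.ssr / full.df_resid
    df_resid = full.df_resid
    contrasts = []
    for day, sub in df.groupby("day"):
        cell = sub.groupby("group")["value"].agg(["mean", "count"])
        for g1, g2 in combinations(sorted(cell.index), 2):
            n1, n2 = cell.loc[g1, "count"], cell.loc[g2, "count"]
            if n1 < 1 or n2 < 1:
                continue
            diff = cell.loc[g1, "mean"] - cell.loc[g2, "mean"]
            se = math.sqrt(mse * (1.0 / n1 + 1.0 / n2))
            t = diff / se if se > 0 else np.nan
            p_raw = float(2.0 * stats.t.sf(abs(t), df_resid)) if np.isfinite(t) else np.nan
            contrasts.append((day, g1, g2, t, p_raw))
    m = len(contrasts)
    for day, g1, g2, t, p_raw in contrasts:
        p_adj = min(1.0, p_raw * m) if np.isfinite(p_raw) else np.nan
        results.append(
            StatResult(
                "bonferroni_pairwise",
                f"{g1} vs {g2} @ day {day}",
                t,
                p_raw,
                p_adjusted=p_adj,
                extras={"family_size": m, "parameter": parameter},
            )
        )
    return results


# ---------------------------------------------------------------------------
# Correlation and logistic regression
# ---------------------------------------------------------------------------

def pearson_volume_correlation(table: pd.DataFrame, group: str, parameter: str) -> StatResult:
    """Pearson r between a parameter and relative liver volume within a group.

    Observations are (animal, day) pairs pooled over all days where both the
    parameter and the volume record exist; p is two-sided from the
    t-distribution with n-2 df.
    """
    sub = table[table["group"] == group]
    par = sub[sub["parameter"] == parameter][["animal_id", "day", "value"]]
    vol = sub[sub["parameter"] == "volume_pct"][["animal_id", "day", "value"]]
    merged = par.merge(vol, on=["animal_id", "day"], suffixes=("_par", "_vol"))
    n = len(merged)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    x = merged["value_par"].to_numpy()
    y = merged["value_vol"].to_numpy()
    if np.std(x) == 0 or np.std(y) == 0:
        return StatResult(
            "pearson", f"{parameter} vs volume ({group})", np.nan, np.nan,
            extras={"n": n, "flag": "zero variance"},
        )
    r, p = stats.pearsonr(x, y)
    return StatResult(
        "pearson", f"{parameter} vs volume ({group})", float(r), float(p), extras={"n": n, "r": float(r)}
    )


def nagelkerke_r2(ll_full: float, ll_null: float, n: int) -> float:
    """Nagelkerke pseudo-R2 from the full and intercept-only log-likelihoods.

    ``R2 = (1 - (L0/L1)^(2/n)) / (1 - L0^(2/n))`` with likelihoods L0, L1.
    """
    cox_snell = 1.0 - math.exp(2.0 * (ll_null - ll_full) / n)
    max_r2 = 1.0 - math.exp(2.0 * ll_null / n)
    if max_r2 <= 0:
        return 0.0
    return min(max(cox_snell / max_r2, 0.0), 1.0)


def plf_logistic_regression(
    table: pd.DataFrame, day: int, predictors=MR_PARAMETERS
) -> StatResult:
    """Logistic regression of fatal liver failure on the day's MR parameters.

    Fits death-by-PLF (the fatal subgroup of the extended-resection animals)
    against the quantitative MR parameters measured on ``day`` for all
    extended-resection animals (ePH + PLF), by maximum likelihood.  Reports
    the coefficients, the likelihood-ratio omnibus test against the
    intercept-only model, and Nagelkerke R2.  Complete separation is flagged
    rather than fatal; R2 is still computed from the likelihoods.
    """
    sub = table[table["group"].isin(["ePH", "PLF"]) & (table["day"] == day)]
    wide = sub[sub["parameter"].isin(predictors)].pivot_table(
        index=["animal_id", "group"], columns="parameter", values="value"
    ).dropna()
    if wide.empty:
        raise ValueError(f"no predictor records on day {day}")
    y = (wide.index.get_level_values("group") == "PLF").astype(float)
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    X = wide.to_numpy()
    # standardize for numerical stability; LR test and R2 are invariant
    Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    Xs = sm.add_constant(Xs, has_constant="add")
    n = len(y)
    separation_flag = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            fit = sm.Logit(y, Xs).fit(disp=0, maxiter=200, method="bfgs")
        except Exception:
            separation_flag = True
            fit = sm.Logit(y, Xs).fit_regularized(disp=0, alpha=1e-6, maxiter=500)
        if any("separation" in str(w.message).lower() or "converge" in str(w.message).lower() for w in caught):
            separation_flag = True
    ll_full = float(fit.llf)
    p_mean = y.mean()
    ll_null = float(n * (p_mean * math.log(p_mean) + (1 - p_mean) * math.log(1 - p_mean)))
    k = Xs.shape[1] - 1
    lr = 2.0 * (ll_full - ll_null)
    p_omnibus = float(stats.chi2.sf(max(lr, 0.0), k))
    r2 = nagelkerke_r2(ll_full, ll_null, n)
    if separation_flag:
        warnings.warn("possible complete separation: coefficients are unstable")
    return StatResult(
        "plf_logistic",
        f"PLF ~ {' + '.join(wide.columns)} @ day {day}",
        lr,
        p_omnibus,
        extras={
            "coefficients": dict(zip(["intercept", *wide.columns], np.asarray(fit.params))),
            "nagelkerke_r2": r2,
            "n": n,
            "separation_flag": separation_flag,
            "ll_full": ll_full,
            "ll_null": ll_null,
        },
    )


# ---------------------------------------------------------------------------
# Abstract percent-change check
# ---------------------------------------------------------------------------

def _load_expected_changes() -> List[dict]:
    text = resources.files("liverquant.data").joinpath(ABSTRACT_CHANGES_FIXTURE).read_text()
    return json.loads(text)


def reproduce_abstract_changes(summary: pd.DataFrame, expected: Optional[List[dict]] = None) -> pd.DataFrame:
    """Check the printed percent-change figures against the group summaries.

    For each fixture row (parameter, day, group, direction, expected integer
    percent) the change of the group mean against its day-0 mean is computed
    with :func:`percent_change` and compared; missing cells are reported as
    missing rather than failed.
    """
    if expected is None:
        expected = _load_expected_changes()
    rows = []
    for item in expected:
        p, day, grp = item["parameter"], item["day"], item["group"]
        base = summary[(summary["parameter"] == p) & (summary["group"] == grp) & (summary["day"] == 0)]
        cell = summary[(summary["parameter"] == p) & (summary["group"] == grp) & (summary["day"] == day)]
        row = dict(item)
        if base.empty or cell.empty:
            row.update(computed=None, status="missing")
        else:
            got = percent_change(base["mean"].iloc[0], cell["mean"].iloc[0], item["direction"])
            row.update(computed=got, status="pass" if got == item["expected"] else "fail")
        rows.append(row)
    return pd.DataFrame(rows)
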