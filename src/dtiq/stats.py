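"""Statistical battery for ROI metric tables and histology counts.

The design is a two-way mixed model: a between-subjects ``group`` factor
and a within-subjects ``timepoint`` factor (two levels, so sphericity
holds trivially and no correction is needed).  Group differences are
followed up with Bonferroni-protected pairwise contrasts (alpha / 3 for
three groups), histology counts with one-way ANOVA plus Tukey HSD
(Tukey-Kramer form for unequal n), and imaging-histology association
with the Pearson correlation and its least-squares line.

The rmANOVA and Tukey routines are explicit sums-of-squares /
studentized-range implementations rather than wrappers: the contracts
here require defined behaviour on degenerate inputs (an effect with zero
sum of squares reports F = 0, p = 1 even when the error stratum is also
empty), which general-purpose wrappers return as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EffectStat",
    "RmAnovaResult",
    "CorrelationResult",
    "rm_anova",
    "posthoc_bonferroni",
    "oneway_anova_tukey",
    "pearson_with_regression",
]

_SS_TOL = 1e-12  # relative tolerance declaring a sum of squares exactly zero


@dataclass(frozen=True)
class EffectStat:
    """One F test: statistic, p-value and its degrees of freedom."""

    F: float
    p: float
    df1: int
    df2: int
    ss_effect: float
    ss_error: float


@dataclass(frozen=True)
class RmAnovaResult:
    """Mixed-design ANOVA decomposition for one ROI x metric cell."""

    group: EffectStat
    time: EffectStat
    interaction: EffectStat
    cell_means: pd.DataFrame  # columns group, timepoint, mean, n

    def effect(self, name: str) -> EffectStat:
        return {"group": self.group, "time": self.time, "interaction": self.interaction}[name]


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with the matching least-squares line."""

    r: float
    p: float
    n: int
    slope: float
    intercept: float
    r_squared: float


def _f_test(ss_effect, df1, ss_error, df2, ss_scale) -> EffectStat:
    """F ratio with the zero-SS convention: a numerator that vanishes (to
    relative tolerance) is reported as F = 0, p = 1 regardless of the
    error stratum; a vanishing error under a real effect is F = inf."""
    tol = _SS_TOL * max(ss_scale, 1e-300)
    if ss_effect <= tol:
        return EffectStat(0.0, 1.0, df1, df2, ss_effect, ss_error)
    if ss_error <= tol or df2 <= 0:
        return EffectStat(np.inf, 0.0, df1, df2, ss_effect, ss_error)
    f = (ss_effect / df1) / (ss_error / df2)
    return EffectStat(float(f), float(sps.f.sf(f, df1, df2)), df1, df2, ss_effect, ss_error)


def _check_design(table: pd.DataFrame, value_col: str) -> pd.DataFrame:
    required = {"subject_id", "group", "timepoint", value_col}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    t = table[["subject_id", "group", "timepoint", value_col]].copy()
    if t[["subject_id", "timepoint"]].duplicated().any():
        raise ValueError(
            "multiple rows per (subject, timepoint); pass a single ROI x metric subset"
        )
    timepoints = list(dict.fromkeys(t["timepoint"]))
    counts = t.groupby("subject_id", sort=False)["timepoint"].nunique()
    incomplete = counts[counts < len(timepoints)]
    if not incomplete.empty:
        raise ValueError(
            f"incomplete design: subjects missing timepoints: {list(incomplete.index)}"
        )
    groups = t.groupby("group", sort=False)["subject_id"].nunique()
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    return t


def rm_anova(table: pd.DataFrame, value_col: str = "value") -> RmAnovaResult:
    """Two-way mixed-design repeated-measures ANOVA.

    Expects one row per (subject, timepoint) with columns ``subject_id``,
    ``group``, ``timepoint`` and ``value_col``; every subject must have
    all timepoints (no imputation).  Classical decomposition: the group
    effect is tested against subjects-within-groups, time and
    group x time against the subject x time error stratum.  Exact for
    balanced group sizes (where all sums-of-squares types coincide).
    """
    t = _check_design(table, value_col)
    y = t[value_col].to_numpy(dtype=float)
    gm = y.mean()
    ss_total = float(((y - gm) ** 2).sum())

    subj = t.groupby("subject_id", sort=False)
    subj_means = subj[value_col].mean()
    subj_group = subj["group"].first()
    n_times = t["timepoint"].nunique()
    n_subj = len(subj_means)
    n_groups = subj_group.nunique()

    ss_between_subj = float(n_times * ((subj_means - gm) ** 2).sum())
    group_means = subj_means.groupby(subj_group, sort=False).mean()
    group_sizes = subj_group.value_counts(sort=False)
    ss_group = float(
        n_times * (group_sizes * (group_means - gm) ** 2).sum()
    )
    ss_subj_within = max(ss_between_subj - ss_group, 0.0)

    merged = t.merge(
        subj_means.rename("subj_mean"), left_on="subject_id", right_index=True
    )
    ss_within_subj = float(((merged[value_col] - merged["subj_mean"]) ** 2).sum())

    time_means = t.groupby("timepoint", sort=False)[value_col].mean()
    ss_time = float(n_subj * ((time_means - gm) ** 2).sum())

    cells = (
        t.groupby(["group", "timepoint"], sort=False)[value_col]
        .agg(["mean", "count"])
        .reset_index()
    )
    inter_dev = (
        cells["mean"].to_numpy()
        - cells["group"].map(group_means).to_numpy()
        - cells["timepoint"].map(time_means).to_numpy()
        + gm
    )
    cell_n = cells["group"].map(group_sizes).to_numpy()
    ss_inter = float((cell_n * inter_dev**2).sum())
    ss_err_within = max(ss_within_subj - ss_time - ss_inter, 0.0)

    df_group, df_subj = n_groups - 1, n_subj - n_groups
    df_time = n_times - 1
    df_inter = df_group * df_time
    df_err = df_subj * df_time

    cell_means = cells.rename(columns={"mean": "mean", "count": "n"})
    return RmAnovaResult(
        group=_f_test(ss_group, df_group, ss_subj_within, df_subj, ss_total),
        time=_f_test(ss_time, df_time, ss_err_within, df_err, ss_total),
        interaction=_f_test(ss_inter, df_inter, ss_err_within, df_err, ss_total),
        cell_means=cell_means,
    )


def _pairwise_t(means, sizes, mse, dfe, n_comparisons, alpha):
    rows = []
    names = list(means.index)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            diff = float(means[a] - means[b])
            se = np.sqrt(mse * (1.0 / sizes[a] + 1.0 / sizes[b]))
            if se == 0:
                tval = np.inf if diff != 0 else 0.0
                p = 0.0 if diff != 0 else 1.0
            else:
                tval = diff / se
                p = float(2 * sps.t.sf(abs(tval), dfe))
            rows.append(
                {
                    "contrast": f"{a} - {b}",
                    "mean_diff": diff,
                    "t": float(tval),
                    "df": dfe,
                    "p_raw": p,
                    "p_bonf": min(1.0, n_comparisons * p),
                    "significant": p < alpha / n_comparisons,
                }
            )
    return rows


def posthoc_bonferroni(
    table: pd.DataFrame,
    alpha: float = 0.05,
    mode: str = "per_day",
    value_col: str = "value",
) -> pd.DataFrame:
    """Bonferroni-protected pairwise group contrasts.

    ``mode='per_day'`` (default) compares groups within each timepoint,
    using that timepoint's pooled within-group variance (df = N - k);
    ``mode='averaged'`` compares subject means averaged over timepoints,
    using the subjects-within-groups stratum.  With three groups each
    contrast is declared significant at raw p < alpha/3; the
    multiplied-and-capped p is reported alongside.
    """
    t = _check_design(table, value_col)
    group_sizes = t.groupby("group", sort=False)["subject_id"].nunique()
    if (group_sizes < 2).any():
        raise ValueError("every group needs >= 2 subjects for post hoc contrasts")
    k = len(group_sizes)
    n_comp = k * (k - 1) // 2

    rows = []
    if mode == "per_day":
        for tp, day in t.groupby("timepoint", sort=False):
            means = day.groupby("group", sort=False)[value_col].mean()
            sizes = day.groupby("group", sort=False)[value_col].count()
            resid = day[value_col] - day["group"].map(means)
            dfe = int(sizes.sum() - k)
            mse = float((resid**2).sum() / dfe) if dfe > 0 else 0.0
            for row in _pairwise_t(means, sizes, mse, dfe, n_comp, alpha):
                rows.append({"timepoint": tp, **row})
    elif mode == "averaged":
        subj = t.groupby("subject_id", sort=False)
        sm = subj[value_col].mean()
        sg = subj["group"].first()
        means = sm.groupby(sg, sort=False).mean()
        resid = sm - sg.map(means)
        dfe = int(len(sm) - k)
        mse = float((resid**2).sum() / dfe) if dfe > 0 else 0.0
        for row in _pairwise_t(means, group_sizes, mse, dfe, n_comp, alpha):
            rows.append({"timepoint": "averaged", **row})
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows)


def oneway_anova_tukey(
    counts: pd.DataFrame, value_col: str = "count", alpha: float = 0.05
) -> tuple[EffectStat, pd.DataFrame]:
    """One-way ANOVA over groups plus Tukey HSD pairwise contrasts.

    Adjusted p-values come from the studentized-range distribution with
    the pooled within-group variance; unequal group sizes use the
    Tukey-Kramer standard error.  All-zero within-group variance is a
    degenerate-variance error.
    """
    if "group" not in counts.columns or value_col not in counts.columns:
        raise ValueError(f"need columns 'group' and {value_col!r}")
    by = counts.groupby("group", sort=False)[value_col]
    sizes = by.count()
    if len(sizes) < 2 or (sizes < 2).any():
        raise ValueError("need >= 2 groups with >= 2 observations each")
    means = by.mean()
    gm = counts[value_col].mean()
    n_total = int(sizes.sum())
    k = len(sizes)
    ss_between = float((sizes * (means - gm) ** 2).sum())
    resid = counts[value_col] - counts["group"].map(means)
    ss_within = float((resid**2).sum())
    if ss_within <= _SS_TOL * max(ss_between, 1.0) and ss_between > 0:
        raise ValueError("degenerate: zero within-group variance everywhere")
    dfe = n_total - k
    anova = _f_test(ss_between, k - 1, ss_within, dfe, ss_between + ss_within)
    msw = ss_within / dfe

    rows = []
    names = list(means.index)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            diff = float(means[a] - means[b])
            se = np.sqrt(msw / 2.0 * (1.0 / sizes[a] + 1.0 / sizes[b]))
            qstat = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(qstat, k, dfe))
            rows.append(
                {
                    "contrast": f"{a} - {b}",
                    "mean_diff": diff,
                    "q": float(qstat),
                    "df": dfe,
                    "p_adj": p_adj,
                    "significant": p_adj < alpha,
                }
            )
    return anova, pd.DataFrame(rows)


def pearson_with_regression(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with the least-squares line.

    Two-sided p via the t transform with n - 2 degrees of freedom.  The
    identity r^2 = R^2 (regression coefficient of determination) is
    verified internally to 1e-12.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need n >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant x or y")
    r, p = sps.pearsonr(x, y)
    reg = sps.linregress(x, y)
    pred = reg.intercept + reg.slope * x
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r_squared = 1.0 - ss_res / ss_tot
    if abs(r_squared - r**2) > 1e-10:
        raise AssertionError("r^2 / R^2 identity violated beyond tolerance")
    return CorrelationResult(
        r=float(r),
        p=float(p),
        n=int(x.size),
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        r_squared=float(r_squared),
    )
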