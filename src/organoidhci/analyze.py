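"""Percent-of-control normalization, replicate aggregation, response
categorization, and group-comparison statistics.

Per-well readouts are normalized to 100 x value / mean(passing control wells
of the same sample), summarized over technical replicates with the
readout-specific convention (median for total volume and object count —
robust to single-well outliers; mean for single-cell count and infiltration),
and the volume reduction 100 - poc is binned into the standard response
categories: <10% non-responder, then 10-30%, 31-50%, 51-70%, >71%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

READOUTS = (
    "total_volume_mm3",
    "object_count",
    "single_cell_count",
    "infiltration_fraction",
)

#: replicate summary convention per readout
_SUMMARY_FN = {
    "total_volume_mm3": np.median,
    "object_count": np.median,
    "single_cell_count": np.mean,
    "infiltration_fraction": np.mean,
}

RESPONSE_CATEGORIES = ("non-responder", "10-30", "31-50", "51-70", ">71")

#: significance stars, strongest first
_STARS = ((0.0001, "****"), (0.005, "***"), (0.01, "**"), (0.05, "*"))


class NormalizationError(ValueError):
    pass


def percent_of_control(
    values: pd.Series | dict[str, float],
    control_wells: list[str],
    exclusions: set[str] | None = None,
    control_summary: str = "mean",
) -> pd.Series:
    """Percent-of-control per well: 100 x value / summary(passing controls).

    Control wells are normalized too, so with the default mean summary the
    control group's mean poc is exactly 100.
    """
    vals = pd.Series(values, dtype=float)
    excl = exclusions or set()
    vals = vals[~vals.index.isin(excl)]
    ctrl = vals[vals.index.isin([c for c in control_wells if c not in excl])]
    if ctrl.empty:
        raise NormalizationError("all control wells excluded; cannot normalize")
    denom = float(ctrl.mean() if control_summary == "mean" else ctrl.median())
    if denom == 0:
        raise NormalizationError("control summary is zero; cannot normalize")
    return 100.0 * vals / denom


def aggregate_replicates(poc: pd.Series | list[float], readout: str) -> dict:
    """Summarize per-well poc values of one replicate group.

    Median for total volume and object count, mean for single-cell count and
    infiltration; SD always emitted; fewer than two surviving replicates are
    flagged ``low_n``.
    """
    vals = np.asarray(pd.Series(poc, dtype=float).dropna())
    if vals.size == 0:
        raise NormalizationError("no surviving replicates to aggregate")
    fn = _SUMMARY_FN.get(readout, np.median)
    return {
        "poc_summary": float(fn(vals)),
        "poc_sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
        "n_replicates": int(vals.size),
        "low_n": bool(vals.size < 2),
    }


def classify_response(reduction_percent: float) -> str:
    """Bin a continuous volume reduction into the stepwise response categories.

    Half-open bins [10, 31), [31, 51), [51, 71), [71, inf); anything below
    10% reduction (including growth, i.e. negative values) is a
    non-responder. Total and monotone over the real line.
    """
    r = float(reduction_percent)
    if not np.isfinite(r):
        raise ValueError("reduction_percent must be finite")
    if r < 10.0:
        return "non-responder"
    if r < 31.0:
        return "10-30"
    if r < 51.0:
        return "31-50"
    if r < 71.0:
        return "51-70"
    return ">71"


def _stars(p: float) -> str:
    for cutoff, mark in _STARS:
        if p < cutoff:
            return mark
    return "ns"


@dataclass
class GroupComparison:
    """ANOVA + post-hoc result."""

    anova: pd.DataFrame  # effect, F, p
    comparisons: pd.DataFrame  # group_1, group_2, mean_diff, p_adj, stars
    method: str


def compare_groups(
    data: pd.DataFrame,
    value: str = "poc",
    group: str = "condition",
    factor2: str | None = None,
    reference: str | None = None,
) -> GroupComparison:
    """Fixed-effects ANOVA on well-level values with adjusted post-hoc tests.

    One-way by default; passing ``factor2`` fits a two-way ANOVA with
    interaction (the post-hoc comparisons then run on the primary factor).
    Post-hoc: all-pairs Tukey HSD (studentized range), or many-to-one
    Dunnett against ``reference`` when given. Groups with fewer than two
    wells are skipped from the post-hoc with a warning.
    """
    import warnings

    df = data[[c for c in (value, group, factor2) if c]].dropna().copy()
    sizes = df.groupby(group)[value].count()
    small = sizes[sizes < 2]
    if len(small):
        warnings.warn(
            f"groups skipped from comparison (n<2): {list(small.index)}", stacklevel=2
        )
        df = df[~df[group].isin(small.index)]
    levels = sorted(df[group].unique())
    if len(levels) < 2:
        raise ValueError("need at least two groups with n >= 2")
    samples = [df.loc[df[group] == g, value].to_numpy(float) for g in levels]
    if all(np.ptp(s) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        raise ValueError("zero variance in every group; ANOVA undefined")

    if factor2 is None:
        f_stat, p = stats.f_oneway(*samples)
        anova = pd.DataFrame(
            [{"effect": group, "F": float(f_stat), "p": float(p)}]
        )
    else:
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        d = df.rename(columns={value: "y", group: "g1", factor2: "g2"})
        model = smf.ols("y ~ C(g1) * C(g2)", data=d).fit()
        table = sm.stats.anova_lm(model, typ=2)
        anova = pd.DataFrame(
            {
                "effect": [group, factor2, f"{group}:{factor2}"],
                "F": table["F"].to_numpy()[:3],
                "p": table["PR(>F)"].to_numpy()[:3],
            }
        )

    rows = []
    if reference is None:
        res = stats.tukey_hsd(*samples)
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                p_adj = float(res.pvalue[i, j])
                rows.append(
                    {
                        "group_1": levels[i],
                        "group_2": levels[j],
                        "mean_diff": float(samples[i].mean() - samples[j].mean()),
                        "p_adj": p_adj,
                        "stars": _stars(p_adj),
                    }
                )
        method = "tukey"
    else:
        if reference not in levels:
            raise ValueError(f"reference group {reference!r} not present")
        ref = df.loc[df[group] == reference, value].to_numpy(float)
        others = [g for g in levels if g != reference]
        # fixed rng: Dunnett's multivariate-t integration is randomized and
        # must not make repeated runs differ
        res = stats.dunnett(
            *[df.loc[df[group] == g, value].to_numpy(float) for g in others],
            control=ref,
            rng=np.random.default_rng(0),
        )
        for g, p_adj in zip(others, np.atleast_1d(res.pvalue)):
            rows.append(
                {
                    "group_1": g,
                    "group_2": reference,
                    "mean_diff": float(
                        df.loc[df[group] == g, value].mean() - ref.mean()
                    ),
                    "p_adj": float(p_adj),
                    "stars": _stars(float(p_adj)),
                }
            )
        method = "dunnett"
    comparisons = pd.DataFrame(
        rows, columns=["group_1", "group_2", "mean_diff", "p_adj", "stars"]
    )
    return GroupComparison(anova=anova, comparisons=comparisons, method=method)


def build_dose_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Long-format dose-response table with monotone-trend flags.

    Expects columns [sample_id, condition, dose, readout, poc_summary];
    within each (sample, condition, readout) series with >= 2 doses, a
    strictly monotone relationship (|Spearman rho| == 1) is flagged as
    "decreasing" or "increasing" by the correlation sign.
    """
    required = {"sample_id", "condition", "dose", "readout", "poc_summary"}
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = summaries.copy()
    df["dose_trend"] = ""
    for key, sub in df.groupby(["sample_id", "condition", "readout"]):
        sub = sub.dropna(subset=["dose"])
        if sub["dose"].nunique() < 2:
            continue
        rho = stats.spearmanr(sub["dose"], sub["poc_summary"]).statistic
        if np.isfinite(rho) and abs(rho) == 1.0:
            df.loc[sub.index, "dose_trend"] = (
                "decreasing" if rho < 0 else "increasing"
            )
    return df.sort_values(["sample_id", "condition", "readout", "dose"]).reset_index(
        drop=True
    )
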