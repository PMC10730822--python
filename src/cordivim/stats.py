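"""Group-comparison statistics for cohort tables.

Implements the study's statistical plan over per-subject ROI means,
morphometry and clinical scores: percent differences between group
means, one/two-tailed two-sample t-tests, a two-way ANOVA
(group x subregion) with per-subregion post-hoc tests, ordinary
least-squares regression with Pearson correlation, and
cohort-demographics tests (Mann-Whitney U on age, Fisher's exact on
sex).  Post-hoc and per-metric tests are uncorrected for multiple
comparisons by default, matching the emulated analysis plan; a
Benjamini-Hochberg switch is available.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "round_half_away",
    "percent_difference",
    "two_sample_ttest",
    "two_way_anova_posthoc",
    "linreg_pearson",
    "demographics_tests",
    "bh_adjust",
    "run_group_study",
]

PERFUSION_METRICS = ("f_wm", "dstar_wm", "fdstar_wm", "d_wm",
                     "f_gm", "dstar_gm", "fdstar_gm", "d_gm")
MORPHOMETRY_METRICS = ("wm_csa", "gm_csa", "ap_diameter", "lr_width")
WM_SUBREGIONS = ("ventral_funiculi", "lateral_funiculi", "dorsal_columns")
GM_SUBREGIONS = ("ventral_horns", "dorsal_horns")


@dataclass
class StatResult:
    """One test's outcome.

    ``estimate`` is the effect measure (mean difference, correlation R,
    F statistic, U, odds ratio — named in ``name``); ``tails`` is
    "one", "two" or "" for tests without a tail notion.
    """

    name: str
    estimate: float
    statistic: float
    p_value: float
    tails: str = "two"
    n1: int = 0
    n2: int = 0
    df: float = math.nan
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p_value must be in [0, 1], got {self.p_value}")
        if self.tails not in ("one", "two", ""):
            raise ValueError(f"tails must be 'one', 'two' or '', got {self.tails!r}")


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (so -6.25 -> -6.3 at one decimal)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def percent_difference(reference_mean: float, test_mean: float,
                       decimals: int | None = 1) -> float:
    """Percent difference of a test-group mean relative to a reference.

    100 * (test - reference) / reference, rounded half-away-from-zero to
    ``decimals`` places (``decimals=None`` returns the raw value).
    """
    if reference_mean == 0:
        raise ValueError("reference mean is zero; percent difference undefined")
    delta = 100.0 * (test_mean - reference_mean) / reference_mean
    return delta if decimals is None else round_half_away(delta, decimals)


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[np.isfinite(x)]


def two_sample_ttest(
    x,
    y,
    tails: str = "two",
    direction: str = "less",
    equal_var: bool = True,
) -> StatResult:
    """Independent two-sample t-test of x versus y.

    ``tails="one"`` tests the directional hypothesis that mean(x) is
    ``direction`` ("less"/"greater") than mean(y); its p-value is half
    the two-tailed p when the observed effect lies in that direction
    and 1 minus that half otherwise.  Pooled-variance (classical) by
    default; ``equal_var=False`` gives the Welch test.
    """
    x, y = _clean(x), _clean(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError(f"each sample needs n >= 2, got {len(x)} and {len(y)}")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("both samples are constant; t statistic undefined")
    if tails not in ("one", "two"):
        raise ValueError(f"tails must be 'one' or 'two', got {tails!r}")
    if direction not in ("less", "greater"):
        raise ValueError(f"direction must be 'less' or 'greater', got {direction!r}")
    alternative = "two-sided" if tails == "two" else direction
    res = sps.ttest_ind(x, y, equal_var=equal_var, alternative=alternative)
    df = float(res.df)
    return StatResult(
        name="two-sample t-test" + ("" if equal_var else " (Welch)"),
        estimate=float(np.mean(x) - np.mean(y)),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        tails=tails,
        n1=len(x),
        n2=len(y),
        df=df,
    )


def two_way_anova_posthoc(
    table: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    subregion: str = "subregion",
    reference_group: str = "HC",
    posthoc_direction: str = "less",
) -> tuple[list[StatResult], list[StatResult]]:
    """Two-way ANOVA (group x subregion) with per-subregion post-hoc tests.

    Fits ``value ~ C(group) * C(subregion)`` by OLS and reports the two
    main-effect F tests and the interaction (type-II sums of squares).
    Post-hoc analysis runs, per subregion, a one-tailed two-sample
    t-test of the non-reference group against ``reference_group`` in
    direction ``posthoc_direction``; p-values are uncorrected.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = table[[value, group, subregion]].dropna().rename(
        columns={value: "value", group: "group", subregion: "subregion"}
    )
    groups = sorted(df["group"].unique())
    regions = sorted(df["subregion"].unique())
    if len(groups) < 2 or len(regions) < 2:
        raise ValueError(
            f"need >= 2 levels per factor, got groups={groups}, subregions={regions}"
        )
    counts = df.groupby(["group", "subregion"]).size()
    empty = [
        (g, r) for g in groups for r in regions
        if counts.get((g, r), 0) < 2
    ]
    if empty:
        raise ValueError(f"cells with fewer than 2 observations: {empty}")

    model = smf.ols("value ~ C(group) * C(subregion)", data=df).fit()
    aov = anova_lm(model, typ=2)
    label_map = {
        "C(group)": "group main effect",
        "C(subregion)": "subregion main effect",
        "C(group):C(subregion)": "group x subregion interaction",
    }
    anova_results = [
        StatResult(
            name=f"ANOVA {label_map[idx]}",
            estimate=float(row["F"]),
            statistic=float(row["F"]),
            p_value=float(row["PR(>F)"]),
            tails="",
            df=float(row["df"]),
            extra={"sum_sq": float(row["sum_sq"]),
                   "df_resid": float(aov.loc["Residual", "df"])},
        )
        for idx, row in aov.iterrows()
        if idx in label_map
    ]

    other = [g for g in groups if g != reference_group]
    posthoc = []
    for region in regions:
        sub = df[df["subregion"] == region]
        ref_vals = sub[sub["group"] == reference_group]["value"]
        for g in other:
            res = two_sample_ttest(
                sub[sub["group"] == g]["value"], ref_vals,
                tails="one", direction=posthoc_direction,
            )
            res.name = f"post-hoc {g} vs {reference_group} in {region}"
            res.extra["subregion"] = region
            posthoc.append(res)
    return anova_results, posthoc


def linreg_pearson(x, y) -> StatResult:
    """OLS regression of y on x with Pearson's correlation coefficient.

    ``estimate`` is R; the slope and intercept are in ``extra``.  The
    two-tailed p comes from the t transform of R with n - 2 df.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError(f"need n >= 3 finite pairs, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; regression undefined")
    res = sps.linregress(x, y)
    return StatResult(
        name="linear regression / Pearson correlation",
        estimate=float(res.rvalue),
        statistic=float(res.rvalue),
        p_value=float(res.pvalue),
        tails="two",
        n1=len(x),
        df=float(len(x) - 2),
        extra={"slope": float(res.slope), "intercept": float(res.intercept),
               "r_squared": float(res.rvalue**2)},
    )


def demographics_tests(table: pd.DataFrame, group_col: str = "group",
                       age_col: str = "age", sex_col: str = "sex") -> tuple[StatResult, StatResult]:
    """Cohort comparability: Mann-Whitney U on age, Fisher's exact on sex.

    Returns (age_result, sex_result).
    """
    groups = sorted(table[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    g1, g2 = groups
    age1 = _clean(table.loc[table[group_col] == g1, age_col])
    age2 = _clean(table.loc[table[group_col] == g2, age_col])
    u = sps.mannwhitneyu(age1, age2, alternative="two-sided")
    age_res = StatResult(
        name=f"Mann-Whitney U on age ({g1} vs {g2})",
        estimate=float(u.statistic),
        statistic=float(u.statistic),
        p_value=float(u.pvalue),
        tails="two",
        n1=len(age1),
        n2=len(age2),
    )
    sexes = sorted(table[sex_col].dropna().unique())
    contingency = np.array([
        [int(((table[group_col] == g) & (table[sex_col] == s)).sum()) for s in sexes]
        for g in groups
    ])
    if contingency.shape != (2, 2):
        raise ValueError(f"sex x group table is not 2x2: {contingency.shape}")
    odds, p = sps.fisher_exact(contingency)
    sex_res = StatResult(
        name=f"Fisher's exact on sex x group",
        estimate=float(odds),
        statistic=float(odds),
        p_value=float(p),
        tails="two",
        n1=int(contingency[0].sum()),
        n2=int(contingency[1].sum()),
        extra={"table": contingency.tolist()},
    )
    return age_res, sex_res


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# study driver


def _group_summary(table: pd.DataFrame, metrics: Sequence[str]) -> pd.DataFrame:
    rows = []
    for metric in metrics:
        for group, sub in table.groupby("group"):
            vals = _clean(sub[metric])
            rows.append({
                "metric": metric,
                "group": group,
                "n": len(vals),
                "mean": vals.mean() if len(vals) else np.nan,
                "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
            })
    return pd.DataFrame(rows)


def _compare(table, metric, tails, direction) -> dict:
    hc = _clean(table.loc[table["group"] == "HC", metric])
    dcm = _clean(table.loc[table["group"] == "DCM", metric])
    row = {"metric": metric, "tails": tails, "n_hc": len(hc), "n_dcm": len(dcm)}
    try:
        res = two_sample_ttest(dcm, hc, tails=tails, direction=direction)
        row.update(
            delta_pct=percent_difference(hc.mean(), dcm.mean()),
            hc_mean=hc.mean(), dcm_mean=dcm.mean(),
            t=res.statistic, df=res.df, p=res.p_value, status="ok",
        )
    except ValueError as exc:
        row.update(delta_pct=np.nan, hc_mean=np.nan, dcm_mean=np.nan,
                   t=np.nan, df=np.nan, p=np.nan, status=f"NA ({exc})")
    return row


def run_group_study(
    table: pd.DataFrame,
    out_dir: str | Path | None = None,
    adjust: bool = False,
) -> dict:
    """Run the full group analysis on a cohort table.

    Expects one row per subject with columns ``group`` ("HC"/"DCM"),
    demographics, morphometry, tissue perfusion metrics and per-
    subregion pseudo-diffusion / blood-flow columns (the layout written
    by :func:`cordivim.phantom.generate_cohort`).  Produces:

    - group means +- SD per metric;
    - HC vs DCM comparisons: percent differences with two-tailed t-tests
      for morphometry and one-tailed (DCM < HC) t-tests for perfusion;
    - two-way ANOVA (group x white-matter subregion) on pseudo-diffusion
      with per-subregion post-hoc tests;
    - regression of grey-/white-matter microvascular volume fraction on
      the tissue's cross-sectional area within each group;
    - demographics tests.

    Underpowered or degenerate comparisons are reported with an NA
    status instead of raising.  With ``adjust=True``, Benjamini-
    Hochberg adjusted p-values are appended to the comparison table.
    Results are returned as a dict of DataFrames / objects and, when
    ``out_dir`` is given, written as TSV plus a JSON summary.
    """
    required = {"group", "age", "sex"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table is missing required columns: {sorted(missing)}")
    for g in ("HC", "DCM"):
        if (table["group"] == g).sum() < 2:
            raise ValueError(f"need >= 2 subjects in group {g}")

    metrics = [m for m in MORPHOMETRY_METRICS + PERFUSION_METRICS if m in table.columns]
    sub_metrics = [f"dstar_{r}" for r in WM_SUBREGIONS + GM_SUBREGIONS
                   if f"dstar_{r}" in table.columns]
    summary = _group_summary(table, metrics + sub_metrics)

    comparisons = []
    for metric in metrics + sub_metrics:
        tails = "two" if metric in MORPHOMETRY_METRICS else "one"
        comparisons.append(_compare(table, metric, tails, "less"))
    comparisons = pd.DataFrame(comparisons)
    if adjust:
        ok = comparisons["status"] == "ok"
        comparisons.loc[ok, "p_bh"] = bh_adjust(comparisons.loc[ok, "p"])

    # two-way ANOVA on white-matter subregion pseudo-diffusion
    anova_out: dict = {"status": "NA"}
    long_rows = []
    for r in WM_SUBREGIONS:
        col = f"dstar_{r}"
        if col in table.columns:
            for _, row in table.iterrows():
                long_rows.append({"value": row[col], "group": row["group"], "subregion": r})
    if long_rows:
        long = pd.DataFrame(long_rows).dropna()
        try:
            main, posthoc = two_way_anova_posthoc(long)
            anova_out = {"status": "ok", "main": main, "posthoc": posthoc}
        except ValueError as exc:
            anova_out = {"status": f"NA ({exc})"}

    regressions = []
    for tissue, csa in (("gm", "gm_csa"), ("wm", "wm_csa")):
        fcol = f"f_{tissue}"
        if fcol not in table.columns or csa not in table.columns:
            continue
        for group, sub in table.groupby("group"):
            row = {"tissue": tissue, "group": group}
            try:
                res = linreg_pearson(sub[csa], sub[fcol])
                row.update(R=res.estimate, p=res.p_value, slope=res.extra["slope"],
                           n=res.n1, status="ok")
            except ValueError as exc:
                row.update(R=np.nan, p=np.nan, slope=np.nan, n=len(sub),
                           status=f"NA ({exc})")
            regressions.append(row)
    regressions = pd.DataFrame(regressions)

    try:
        demo = demographics_tests(table)
    except ValueError as exc:
        demo = None

    out = {
        "group_means": summary,
        "comparisons": comparisons,
        "anova": anova_out,
        "regressions": regressions,
        "demographics": demo,
    }
    if out_dir is not None:
        _write_report(out, Path(out_dir))
    return out


def _write_report(out: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    out["group_means"].to_csv(out_dir / "group_means.tsv", sep="\t", index=False)
    out["comparisons"].to_csv(out_dir / "comparisons.tsv", sep="\t", index=False)
    out["regressions"].to_csv(out_dir / "regressions.tsv", sep="\t", index=False)

    summary: dict = {"anova": {"status": out["anova"]["status"]}}
    if out["anova"]["status"] == "ok":
        summary["anova"]["main"] = [asdict(r) for r in out["anova"]["main"]]
        summary["anova"]["posthoc"] = [asdict(r) for r in out["anova"]["posthoc"]]
        posthoc_df = pd.DataFrame(
            [{"subregion": r.extra["subregion"], "t": r.statistic,
              "p": r.p_value, "estimate": r.estimate} for r in out["anova"]["posthoc"]]
        )
        posthoc_df.to_csv(out_dir / "anova_posthoc.tsv", sep="\t", index=False)
    if out["demographics"] is not None:
        summary["demographics"] = [asdict(r) for r in out["demographics"]]
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
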