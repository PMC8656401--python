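"""Group-level statistics on landscape and dynamics metrics.

One-way ANOVA with Bonferroni-corrected pairwise Welch t-tests (verified
alongside by Kruskal-Wallis for non-normal data), Pearson chi-squared for
categorical factors, two-way ANOVA (group x site) with type-II sums of
squares, and ordinary-least-squares regression of symptom scores on basin
characteristics.

Significance is flagged at the 0.05 / 0.01 / 0.005 star levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

STAR_LEVELS = (0.05, 0.01, 0.005)


def significance_stars(p: float) -> str:
    """'' / '*' / '**' / '***' at p < 0.05, 0.01, 0.005."""
    if np.isnan(p):
        return ""
    return "*" * sum(p < level for level in STAR_LEVELS)


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    t_statistic: float
    p_raw: float
    p_adjusted: float
    stars: str


@dataclass
class GroupComparison:
    """One-way ANOVA omnibus + Bonferroni pairwise layer + Kruskal-Wallis."""

    metric: str
    group_summary: pd.DataFrame  # index group, columns n/mean/sd
    f_statistic: float
    p_omnibus: float
    pairwise: list[PairwiseComparison]
    kruskal_h: float
    kruskal_p: float
    degenerate: bool = False  # zero within-group variance everywhere

    @property
    def stars(self) -> str:
        return significance_stars(self.p_omnibus)


def anova_bonferroni(
    values_by_group: Mapping[str, Sequence[float]], metric: str = ""
) -> GroupComparison:
    """One-way ANOVA across groups, pairwise Welch t-tests with Bonferroni.

    The Bonferroni-adjusted p is min(1, raw p * number of pairwise
    comparisons).  Kruskal-Wallis is computed on the same data as a
    distribution-free check.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} needs n >= 2")
        if not np.isfinite(v).all():
            raise ValueError(f"group {g!r} contains non-finite values")
    labels = list(groups)
    arrays = [groups[g] for g in labels]

    degenerate = all(np.ptp(a) == 0 for a in arrays)
    if degenerate:
        f_stat, p_omni = np.nan, np.nan
    else:
        f_stat, p_omni = sps.f_oneway(*arrays)

    n_pairs = len(labels) * (len(labels) - 1) // 2
    pairwise = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            if np.ptp(groups[a]) == 0 and np.ptp(groups[b]) == 0:
                t, p = np.nan, np.nan
            else:
                t, p = sps.ttest_ind(groups[a], groups[b], equal_var=False)
            p_adj = min(1.0, p * n_pairs) if np.isfinite(p) else np.nan
            pairwise.append(
                PairwiseComparison(a, b, float(t), float(p), float(p_adj),
                                   significance_stars(p_adj))
            )

    try:
        h, kp = sps.kruskal(*arrays)
    except ValueError:  # all values identical
        h, kp = np.nan, np.nan

    summary = pd.DataFrame(
        {
            "n": [len(groups[g]) for g in labels],
            "mean": [groups[g].mean() for g in labels],
            "sd": [groups[g].std(ddof=1) for g in labels],
        },
        index=pd.Index(labels, name="group"),
    )
    return GroupComparison(
        metric=metric,
        group_summary=summary,
        f_statistic=float(f_stat),
        p_omnibus=float(p_omni),
        pairwise=pairwise,
        kruskal_h=float(h),
        kruskal_p=float(kp),
        degenerate=degenerate,
    )


def chi_squared(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-squared test of independence on a contingency table.

    Continuity correction is off by default (the plain Pearson statistic).
    """
    table = np.asarray(table, dtype=float)
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("table must hold nonnegative integer counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal row/column")
    if table.sum() == 0:
        raise ValueError("empty table")
    res = sps.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def two_way_anova(
    df: pd.DataFrame,
    value: str,
    group_col: str = "group",
    site_col: str = "site",
) -> pd.DataFrame:
    """Two-way ANOVA (group x site) with type-II sums of squares.

    Returns the statsmodels ANOVA table with rows for the group and site main
    effects, their interaction, and the residual.  Raises on factors with a
    single level or on empty design cells (naming the cell).
    """
    for col in (value, group_col, site_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} missing")
    for col in (group_col, site_col):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs >= 2 levels")
    cells = df.groupby([group_col, site_col], observed=True).size()
    full = pd.MultiIndex.from_product(
        [df[group_col].unique(), df[site_col].unique()], names=[group_col, site_col]
    )
    empty = full.difference(cells.index)
    if len(empty):
        raise ValueError(f"empty design cell(s): {list(empty)}")
    data = df[[value, group_col, site_col]].rename(
        columns={value: "y", group_col: "g", site_col: "s"}
    )
    model = smf.ols("y ~ C(g) * C(s)", data=data).fit()
    table = anova_lm(model, typ=2)
    table.index = ["group", "site", "group:site", "residual"]
    return table


@dataclass
class RegressionResult:
    """OLS fit of a symptom score on basin-characteristic predictors."""

    response: str
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r_squared: float
    nobs: int


def symptom_regression(
    df: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
) -> RegressionResult:
    """OLS of a symptom score on basin characteristics, with intercept.

    Complete cases only; requires at least p + 2 observations for p
    predictors and a full-rank design (collinear columns are named).
    """
    cols = [response, *predictors]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"column(s) missing: {missing}")
    data = df[cols].dropna()
    p = len(predictors)
    if len(data) < p + 2:
        raise ValueError(f"need >= {p + 2} complete cases, have {len(data)}")
    X = sm.add_constant(data[list(predictors)].astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify a minimal set of columns whose removal restores full rank
        collinear = []
        keep = list(X.columns)
        for col in list(predictors):
            trial = [c for c in keep if c != col]
            if np.linalg.matrix_rank(X[trial].to_numpy()) == np.linalg.matrix_rank(
                X[keep].to_numpy()
            ):
                collinear.append(col)
                keep = trial
        raise ValueError(f"rank-deficient design; collinear column(s): {collinear}")
    fit = sm.OLS(data[response].astype(float), X).fit()
    return RegressionResult(
        response=response,
        params=fit.params,
        bse=fit.bse,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        r_squared=float(fit.rsquared),
        nobs=int(fit.nobs),
    )


def comparison_report(comparisons: Sequence[GroupComparison]) -> str:
    """Plain-text table of group means +/- SD with omnibus and pairwise stars."""
    lines = []
    for c in comparisons:
        lines.append(f"== {c.metric} ==")
        for g, row in c.group_summary.iterrows():
            lines.append(
                f"  {g}: {row['mean']:.4f} +/- {row['sd']:.4f} (n={int(row['n'])})"
            )
        if c.degenerate:
            lines.append("  one-way ANOVA: undefined (zero variance everywhere)")
        else:
            lines.append(
                f"  one-way ANOVA: F={c.f_statistic:.4f}, p={c.p_omnibus:.4g} {c.stars}"
            )
        lines.append(
            f"  Kruskal-Wallis: H={c.kruskal_h:.4f}, p={c.kruskal_p:.4g}"
        )
        for pw in c.pairwise:
            lines.append(
                f"  {pw.group_a} vs {pw.group_b}: t={pw.t_statistic:.3f}, "
                f"p_adj={pw.p_adjusted:.4g} {pw.stars}"
            )
        lines.append("")
    return "\n".join(lines)
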