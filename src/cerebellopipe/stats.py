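"""Nonparametric statistical battery for pre/post and group comparisons.

Paired Wilcoxon signed-rank and unpaired Mann-Whitney U tests (exact
small-sample distributions when there are no ties, normal approximation
with tie correction otherwise), Kruskal-Wallis with Dunn's pairwise
z-tests under Holm-Sidak adjustment, two-way ANOVA with interaction
(type-II sums of squares), and the boxplot summary convention (whiskers
at 1.5x the interquartile range).

All tests are two-sided; significance stars map p < 0.05 / 0.01 / 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class PairedComparison:
    unit_ids: tuple
    pre_values: np.ndarray
    post_values: np.ndarray
    effect: float  # median of (post - pre)
    statistic: float
    p_value: float
    test: str = "wilcoxon"


@dataclass(frozen=True)
class GroupComparison:
    group_labels: tuple
    statistic: float
    p_value: float
    test: str
    posthoc: list = field(default_factory=list)  # (pair, z, p_raw, p_adj)


def stars(p: float) -> str:
    """Figure-legend star annotation for a p-value."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_pre_post(pre, post, unit_ids=None) -> PairedComparison:
    """Paired Wilcoxon signed-rank test of post vs pre.

    Exact distribution when there are no ties or zero differences and
    n <= 25; all-zero differences give p = 1 and effect 0.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size != post.size:
        raise ValueError("pre and post must be paired (equal length)")
    if pre.size < 5:
        raise ValueError("need >= 5 pairs for a paired comparison")
    if unit_ids is None:
        unit_ids = tuple(range(pre.size))
    diff = post - pre
    effect = float(np.median(diff))
    if np.all(diff == 0):
        return PairedComparison(tuple(unit_ids), pre, post, 0.0,
                                float("nan"), 1.0)
    nz = diff[diff != 0]
    exact = (nz.size <= 25
             and np.unique(np.abs(nz)).size == nz.size
             and nz.size == diff.size)
    res = sps.wilcoxon(post, pre, alternative="two-sided",
                       method="exact" if exact else "approx",
                       correction=not exact)
    return PairedComparison(tuple(unit_ids), pre, post, effect,
                            float(res.statistic), float(res.pvalue))


def compare_groups(a, b, labels=("a", "b")) -> GroupComparison:
    """Two-sided Mann-Whitney U test of two independent samples.

    Exact when both samples are small (n, m <= 25) with no ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need data")
    pooled = np.concatenate([a, b])
    exact = (max(a.size, b.size) <= 25
             and np.unique(pooled).size == pooled.size)
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    return GroupComparison(tuple(labels), float(res.statistic),
                           float(res.pvalue), "mann-whitney")


def _dunn_pairwise(groups: list[np.ndarray]) -> list[tuple]:
    """Dunn's z statistics and raw two-sided p-values on pooled ranks,
    with the standard tie correction."""
    sizes = np.array([g.size for g in groups])
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks = []
    start = 0
    for size in sizes:
        mean_ranks.append(ranks[start:start + size].mean())
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    out = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(max(var_base, 0.0)
                         * (1.0 / sizes[i] + 1.0 / sizes[j]))
            if se == 0.0:  # fully tied data: no rank variation at all
                z = 0.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            out.append(((i, j), float(z), float(min(p, 1.0))))
    return out


def kruskal_dunn(groups, labels=None) -> GroupComparison:
    """Kruskal-Wallis H test followed by Dunn's pairwise z-tests with
    Holm-Sidak adjustment.

    Four identical groups give H near 0 and all adjusted p-values 1;
    adjusted p-values never drop below the raw ones.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("need >= 3 groups (use compare_groups for 2)")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs >= 2 values")
    if labels is None:
        labels = tuple(f"g{i}" for i in range(len(groups)))
    if all(np.array_equal(g, groups[0]) for g in groups[1:]) and \
            np.unique(groups[0]).size == 1:
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*groups)
    pairwise = _dunn_pairwise(groups)
    raw = [pr for _, _, pr in pairwise]
    adj = multipletests(raw, method="holm-sidak")[1] if raw else []
    posthoc = [
        ((labels[i], labels[j]), z, p_raw, float(max(p_adj, p_raw)))
        for ((i, j), z, p_raw), p_adj in zip(pairwise, adj)
    ]
    return GroupComparison(tuple(labels), float(h), float(p),
                           "kruskal-wallis+dunn", posthoc)


def two_way_anova(values, factor_state, factor_genotype) -> pd.DataFrame:
    """Two-way ANOVA with interaction, type-II sums of squares.

    Returns a table indexed by ``state``, ``genotype``,
    ``state:genotype`` and ``Residual`` with sum_sq, df, F and p columns.
    Requires >= 2 levels per factor and >= 2 observations per cell.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({
        "y": np.asarray(values, dtype=float),
        "state": pd.Categorical(factor_state),
        "genotype": pd.Categorical(factor_genotype),
    })
    if df["state"].nunique() < 2 or df["genotype"].nunique() < 2:
        raise ValueError("need >= 2 levels per factor")
    cell_counts = df.groupby(["state", "genotype"], observed=True).size()
    if (cell_counts < 2).any():
        raise ValueError("need >= 2 observations per cell")
    model = smf.ols("y ~ C(state) * C(genotype)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table.index = ["state", "genotype", "state:genotype", "Residual"]
    return table.rename(columns={"PR(>F)": "p"})


def repeated_measures_anova(values, subject, within) -> pd.DataFrame:
    """One-way repeated-measures ANOVA (each subject measured at every
    level of the within factor).

    Provided as a documented alternative for factorial designs where the
    same units are re-measured across states; the default comparison path
    uses the rank tests and :func:`two_way_anova` instead.
    """
    from statsmodels.stats.anova import AnovaRM

    df = pd.DataFrame({
        "y": np.asarray(values, dtype=float),
        "subject": list(subject),
        "within": list(within),
    })
    res = AnovaRM(df, depvar="y", subject="subject",
                  within=["within"]).fit()
    return res.anova_table.rename(columns={"Pr > F": "p"})


@dataclass(frozen=True)
class BoxplotSummary:
    q1: float
    median: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def boxplot_summary(values) -> BoxplotSummary:
    """Quartiles plus whiskers at the most extreme data within 1.5 IQR of
    the box; values beyond the whiskers are listed as outliers.

    Quartiles use linear interpolation (values 1..100 give
    Q1 = 25.75, median = 50.5, Q3 = 75.25).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty data")
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_bound, hi_bound = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_bound) & (x <= hi_bound)]
    return BoxplotSummary(
        q1=float(q1), median=float(med), q3=float(q3),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        outliers=np.sort(x[(x < lo_bound) | (x > hi_bound)]),
    )
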