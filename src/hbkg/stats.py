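"""Descriptive and inferential statistics on the Hb/kg index.

Stratified group comparisons (Student t, one-way ANOVA with eta-squared and
Scheffe post-hoc), Pearson correlation with age, and mass Spearman screening
of candidate predictors. Summary-statistic entry points (means/SDs/ns) are
first-class so published tables can be checked without row-level data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "ScreeningResult",
    "compare_two_groups",
    "compare_k_groups",
    "t_from_summary",
    "anova_from_summary",
    "pooled_mean",
    "correlate_age",
    "screen_predictors",
    "benjamini_hochberg",
    "scheffe_pairs",
]


@dataclass
class GroupComparison:
    """Result of a two-group t test or a k-group one-way ANOVA."""

    stratification: str
    group_labels: list
    group_ns: list
    group_means: list
    group_sds: list
    statistic: float  # t (two groups) or F (k groups)
    dfs: tuple  # (df,) for t, (df_between, df_within) for ANOVA
    p_value: float
    eta_squared: float | None = None
    posthoc_pairs: list = field(default_factory=list)  # [((i, j), p), ...]
    degenerate: bool = False


@dataclass
class ScreeningResult:
    predictor: str
    rho: float
    p_value: float
    retained: bool


def _group_summaries(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = list(pd.unique(labels))
    groups = [values[labels == u] for u in uniq]
    return uniq, groups


def compare_two_groups(values, labels, stratification: str = "",
                       equal_var: bool = True) -> GroupComparison:
    """Two-sample t test on the index across a binary stratification.

    Student (pooled-variance) t by default, df = n1 + n2 - 2, matching the
    published degrees of freedom; Welch available via ``equal_var=False``.
    """
    uniq, groups = _group_summaries(values, labels)
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(uniq)}")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    n1, n2 = len(groups[0]), len(groups[1])
    pooled_var = (np.var(groups[0], ddof=1) * (n1 - 1)
                  + np.var(groups[1], ddof=1) * (n2 - 1))
    if pooled_var == 0:
        return GroupComparison(stratification, uniq, [n1, n2],
                               [g.mean() for g in groups],
                               [g.std(ddof=1) for g in groups],
                               np.nan, (n1 + n2 - 2,), np.nan, degenerate=True)
    res = sps.ttest_ind(groups[0], groups[1], equal_var=equal_var)
    df = n1 + n2 - 2 if equal_var else float(res.df)
    return GroupComparison(
        stratification, uniq, [n1, n2],
        [float(g.mean()) for g in groups],
        [float(g.std(ddof=1)) for g in groups],
        float(res.statistic), (float(df),), float(res.pvalue),
    )


def scheffe_pairs(groups: Sequence[np.ndarray]) -> list:
    """Scheffe all-pairs post-hoc p-values after a one-way ANOVA.

    For pair (i, j) the test statistic is the pairwise F projection
    (diff^2 / (MSE (1/ni + 1/nj))) / (k - 1), referred to F(k-1, N-k).
    Conservative for all contrasts by construction.
    """
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    N = ns.sum()
    means = np.array([g.mean() for g in groups])
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    mse = ss_within / (N - k)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            if mse == 0:
                out.append(((i, j), np.nan))
                continue
            f_pair = (means[i] - means[j]) ** 2 / (mse * (1 / ns[i] + 1 / ns[j]))
            p = float(sps.f.sf(f_pair / (k - 1), k - 1, N - k))
            out.append(((i, j), p))
    return out


def compare_k_groups(values, labels, stratification: str = "") -> GroupComparison:
    """One-way ANOVA with eta-squared effect size and Scheffe post-hoc."""
    uniq, groups = _group_summaries(values, labels)
    k = len(uniq)
    if k < 3:
        raise ValueError("use compare_two_groups for fewer than 3 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs n >= 2")
    N = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_total = sum(((g - grand) ** 2).sum() for g in groups)
    if ss_total == 0:
        return GroupComparison(stratification, uniq, [len(g) for g in groups],
                               [g.mean() for g in groups],
                               [g.std(ddof=1) for g in groups],
                               np.nan, (k - 1, N - k), np.nan,
                               eta_squared=0.0, degenerate=True)
    f, p = sps.f_oneway(*groups)
    return GroupComparison(
        stratification, uniq, [len(g) for g in groups],
        [float(g.mean()) for g in groups],
        [float(g.std(ddof=1)) for g in groups],
        float(f), (k - 1, N - k), float(p),
        eta_squared=float(ss_between / ss_total),
        posthoc_pairs=scheffe_pairs(groups),
    )


def t_from_summary(mean1, sd1, n1, mean2, sd2, n2):
    """Pooled-variance t and two-sided p from published group summaries."""
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    t = (mean1 - mean2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return float(t), float(2 * sps.t.sf(abs(t), df)), df


def anova_from_summary(means, sds, ns):
    """One-way ANOVA F, p, dfs and eta-squared from published summaries."""
    means, sds, ns = (np.asarray(a, dtype=float) for a in (means, sds, ns))
    k, N = len(means), int(ns.sum())
    grand = (ns * means).sum() / N
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = ((ns - 1) * sds**2).sum()
    f = (ss_between / (k - 1)) / (ss_within / (N - k))
    p = float(sps.f.sf(f, k - 1, N - k))
    eta2 = float(ss_between / (ss_between + ss_within))
    return float(f), p, (k - 1, N - k), eta2


def pooled_mean(means, ns) -> float:
    """Cohort mean implied by a partition's group means and sizes."""
    means, ns = np.asarray(means, float), np.asarray(ns, float)
    return float((means * ns).sum() / ns.sum())


def correlate_age(values, age):
    """Pearson correlation between the index and age; (r, p)."""
    values, age = np.asarray(values, float), np.asarray(age, float)
    if len(values) < 3:
        raise ValueError("need n >= 3")
    if np.std(values) == 0 or np.std(age) == 0:
        return np.nan, np.nan
    r, p = sps.pearsonr(values, age)
    return float(r), float(p)


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    return adj


def screen_predictors(
    table: pd.DataFrame,
    target,
    predictors: Sequence[str] | None = None,
    alpha: float = 0.05,
    bh: bool = False,
) -> pd.DataFrame:
    """Spearman screening of candidate predictors against the index.

    Tie-corrected Spearman rho with the large-sample t approximation for p.
    Retention is raw ``p < alpha`` by default (no multiplicity correction,
    matching common screening practice); ``bh=True`` retains on BH-adjusted
    p-values instead. All-constant predictors are excluded with a flag.

    Returns a tidy frame: predictor, rho, p_value, retained, degenerate.
    """
    y = np.asarray(target, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("target must have at least 2 distinct values")
    cols = list(predictors) if predictors is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    X = table[cols].to_numpy(dtype=float)
    n = len(y)
    degenerate = np.array([len(np.unique(X[:, j])) < 2 for j in range(X.shape[1])])

    # rank-transform once, then correlate column-wise (fast for wide screens)
    ry = sps.rankdata(y)
    rX = sps.rankdata(X, axis=0)
    ry_c = ry - ry.mean()
    rX_c = rX - rX.mean(axis=0)
    denom = np.sqrt((rX_c**2).sum(axis=0) * (ry_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rX_c * ry_c[:, None]).sum(axis=0) / denom
        tstat = rho * np.sqrt((n - 2) / np.maximum(1 - rho**2, 1e-300))
    pvals = 2 * sps.t.sf(np.abs(tstat), n - 2)
    pvals = np.where(np.abs(rho) >= 1.0, 0.0, pvals)
    rho[degenerate] = np.nan
    pvals[degenerate] = np.nan

    crit = pvals.copy()
    if bh:
        ok = ~degenerate
        crit[ok] = benjamini_hochberg(pvals[ok])
    retained = (crit < alpha) & ~degenerate
    return pd.DataFrame({
        "predictor": cols,
        "rho": rho,
        "p_value": pvals,
        "retained": retained,
        "degenerate": degenerate,
    })
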