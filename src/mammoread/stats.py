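"""Discriminative-feature statistics: top-5 aggregation and group tests.

Per outer fold the model records its top-10 important features; the
five names appearing most frequently across all folds are the
pipeline's discriminative features. Their easy-vs-difficult
distributions (of the original, unstandardized values) are compared
with the two-tailed Mann-Whitney U test under a Bonferroni family-wise
error rate of .05 (family size = the 5 tested features), and
summarized as median with interquartile range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class FeatureComparison:
    """One feature's easy-vs-difficult comparison."""

    feature: str
    easy_median: float
    easy_iqr: tuple
    difficult_median: float
    difficult_iqr: tuple
    u_statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool


def aggregate_top_features(per_fold_rankings, n_top: int = 5):
    """Most frequent features across the folds' top-10 lists.

    Returns ``(names, table)``; ties on frequency break by mean within-
    fold rank (lower is better) then by name, so the outcome is
    deterministic.
    """
    freq: dict[str, int] = {}
    rank_sum: dict[str, int] = {}
    n_folds = 0
    for ranking in per_fold_rankings:
        if len(ranking) > 10:
            raise ValueError("each fold contributes at most 10 features")
        n_folds += 1
        for rank, name in enumerate(ranking):
            freq[name] = freq.get(name, 0) + 1
            rank_sum[name] = rank_sum.get(name, 0) + rank
    table = pd.DataFrame({
        "feature": list(freq),
        "frequency": [freq[n] for n in freq],
        "mean_rank": [rank_sum[n] / freq[n] for n in freq],
    })
    table = table.sort_values(["frequency", "mean_rank", "feature"],
                              ascending=[False, True, True],
                              kind="stable").reset_index(drop=True)
    if len(table) < n_top:
        warnings.warn(f"only {len(table)} distinct features recorded; "
                      f"returning all")
    names = table["feature"].head(n_top).tolist()
    return names, table


def mann_whitney(easy_values, difficult_values):
    """Two-tailed Mann-Whitney U (exact when combined n <= 20)."""
    a = np.asarray(easy_values, dtype=float)
    b = np.asarray(difficult_values, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if (a.size + b.size) <= 20 else "asymptotic"
    if method == "exact" and (len(np.unique(np.concatenate([a, b])))
                              < a.size + b.size):
        method = "asymptotic"  # exact distribution is invalid under ties
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bonferroni(p_values, fwer: float = 0.05):
    """Bonferroni-adjusted p-values and strict-< significance flags."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    _, p_adj, _, _ = multipletests(p, alpha=fwer, method="bonferroni")
    return p_adj, p_adj < fwer


def summarize_distribution(values):
    """Median and (p25, p75) IQR by linear interpolation."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty value set")
    q25, q50, q75 = np.percentile(x, [25, 50, 75])
    return float(q50), (float(q25), float(q75))


def compare_discriminative_features(feature_table: pd.DataFrame,
                                    labels, per_fold_rankings,
                                    n_top: int = 5,
                                    fwer: float = 0.05):
    """Full comparison report for the aggregated top features.

    ``feature_table`` holds original (unstandardized) feature values,
    one row per area; ``labels`` is 0 = easy, 1 = difficult.
    """
    labels = np.asarray(labels).astype(int)
    names, _ = aggregate_top_features(per_fold_rankings, n_top)
    comparisons = []
    raw_ps = []
    for name in names:
        easy = feature_table.loc[labels == 0, name].to_numpy()
        diff = feature_table.loc[labels == 1, name].to_numpy()
        u, p = mann_whitney(easy, diff)
        raw_ps.append(p)
        em, eiqr = summarize_distribution(easy)
        dm, diqr = summarize_distribution(diff)
        comparisons.append((name, em, eiqr, dm, diqr, u, p))
    p_adj, sig = bonferroni(raw_ps, fwer)
    out = [FeatureComparison(feature=c[0], easy_median=c[1], easy_iqr=c[2],
                             difficult_median=c[3], difficult_iqr=c[4],
                             u_statistic=c[5], p_raw=c[6],
                             p_adjusted=float(pa), significant=bool(s))
           for c, pa, s in zip(comparisons, p_adj, sig)]
    return out


def comparison_table(comparisons, error_type=None, cohort=None) -> pd.DataFrame:
    """Tidy report: feature, group medians (IQR), adjusted p, stars."""
    rows = []
    for c in comparisons:
        stars = ("**" if c.p_adjusted < 0.005
                 else "*" if c.p_adjusted < 0.05 else "")
        rows.append({
            "error_type": error_type, "cohort": cohort, "feature": c.feature,
            "easy": f"{c.easy_median:.3f} "
                    f"({c.easy_iqr[0]:.3f}-{c.easy_iqr[1]:.3f})",
            "difficult": f"{c.difficult_median:.3f} "
                         f"({c.difficult_iqr[0]:.3f}-{c.difficult_iqr[1]:.3f})",
            "p_adjusted": c.p_adjusted, "significance": stars,
        })
    return pd.DataFrame(rows)
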