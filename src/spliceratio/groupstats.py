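"""Cross-taxa comparisons: permutation tests, Welch tests, CV ratios.

Group differences in splicing ratios and genomic-composition variables are
assessed two ways: Welch's heteroscedasticity-robust t/ANOVA, and Monte
Carlo permutation tests on the mean and the median (the latter robust to
the heavy right tails these variables show).  The permutation p-value is
the plain proportion of label shuffles whose statistic difference is at
least as extreme as the observed one; pairwise batteries are Bonferroni
corrected.

Relative variability is compared with the coefficient of variation
(CV = s / x_bar, sample standard deviation over sample mean) and the CV
ratio CV_x / CV_y: a ratio above 1 means trait x varies more across
species than trait y within the group.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SpliceRatioError

_STATS = {"mean": np.mean, "median": np.median}


@dataclass
class PermResult:
    """Outcome of one permutation test."""

    statistic: str
    observed_diff: float
    p_empirical: float
    n_perm: int
    seed: int | None
    exhaustive: bool = False


def perm_test(
    a,
    b,
    statistic: str = "mean",
    n_perm: int = 10_000,
    seed: int | None = None,
    two_sided: bool = True,
    exhaustive: bool = False,
    plus_one: bool = False,
) -> PermResult:
    """Permutation test for a difference in group mean or median.

    Group labels are shuffled ``n_perm`` times; the empirical p-value is
    the proportion of shuffles whose statistic difference is greater than
    or equal to the observed one (absolute differences when
    ``two_sided``).  ``exhaustive`` enumerates every label assignment
    instead of sampling (feasible for small groups); ``plus_one`` applies
    the (k+1)/(n+1) correction so p is never exactly 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if statistic not in _STATS:
        raise ValueError(f"statistic must be one of {sorted(_STATS)}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    fn = _STATS[statistic]

    observed = fn(a) - fn(b)
    crit = abs(observed) if two_sided else observed
    pooled = np.concatenate([a, b])
    na, n = len(a), len(a) + len(b)

    if exhaustive:
        diffs = np.array(
            [
                fn(pooled[list(idx)])
                - fn(np.delete(pooled, list(idx)))
                for idx in combinations(range(n), na)
            ]
        )
        n_draws = len(diffs)
    else:
        rng = np.random.default_rng(seed)
        # one shuffled copy of the pooled sample per permutation
        order = np.argsort(rng.random((n_perm, n)), axis=1)
        perm = pooled[order]
        diffs = fn(perm[:, :na], axis=1) - fn(perm[:, na:], axis=1)
        n_draws = n_perm

    side = np.abs(diffs) if two_sided else diffs
    k = int(np.sum(side >= crit))
    p = (k + 1) / (n_draws + 1) if plus_one else k / n_draws
    return PermResult(
        statistic=statistic,
        observed_diff=float(observed),
        p_empirical=float(p),
        n_perm=n_draws,
        seed=seed,
        exhaustive=exhaustive,
    )


def bonferroni(pvals) -> list[float]:
    """Bonferroni adjustment: p_adj = min(1, m * p) for m tests."""
    pvals = list(pvals)
    for p in pvals:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
    m = len(pvals)
    return [min(1.0, m * p) for p in pvals]


def welch_pairwise(a, b) -> tuple[float, float, float]:
    """Welch's two-sample t-test: (t, Welch–Satterthwaite df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise SpliceRatioError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def welch_anova(groups: list[np.ndarray]) -> tuple[float, float, float]:
    """Welch's heteroscedastic one-way ANOVA: (F, df_denominator, p).

    Omnibus across k groups; the numerator df is k - 1.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([len(g) for g in groups], dtype=float)
    if np.any(ns < 2):
        raise ValueError("each group needs at least 2 values")
    means = np.array([np.mean(g) for g in groups])
    variances = np.array([np.var(g, ddof=1) for g in groups])
    if np.any(variances == 0):
        raise SpliceRatioError("zero within-group variance in Welch ANOVA")
    w = ns / variances
    grand = np.sum(w * means) / np.sum(w)
    num = np.sum(w * (means - grand) ** 2) / (k - 1)
    tmp = np.sum((1 - w / np.sum(w)) ** 2 / (ns - 1)) / (k**2 - 1)
    den = 1 + 2 * (k - 2) * tmp
    f = num / den
    df2 = 1 / (3 * tmp)
    p = stats.f.sf(f, k - 1, df2)
    return float(f), float(df2), float(p)


def cv(values) -> float:
    """Coefficient of variation s / x_bar (sample sd, n-1 denominator)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("CV needs at least 2 values")
    mean = np.mean(values)
    if mean == 0:
        raise SpliceRatioError("CV undefined: mean is 0")
    if np.ptp(values) == 0:
        return 0.0  # exact, avoiding float cancellation noise in std
    return float(np.std(values, ddof=1) / mean)


def cv_ratio(x, y) -> float:
    """Relative-variability ratio CV_x / CV_y."""
    cvy = cv(y)
    if cvy == 0:
        raise SpliceRatioError("CV ratio undefined: CV of denominator is 0")
    return cv(x) / cvy


def summary_table(
    table: pd.DataFrame,
    group_col: str = "group",
    value_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group mean, [Q0.05, Q0.95] and sample sd for each variable.

    Quantiles interpolate linearly between order statistics.  Groups of a
    single species report sd 0 and are flagged in ``sd_defined``.
    """
    if value_cols is None:
        value_cols = [
            c
            for c in table.columns
            if c != group_col and pd.api.types.is_numeric_dtype(table[c])
        ]
    rows = []
    for group, sub in table.groupby(group_col, sort=True):
        for col in value_cols:
            v = sub[col].dropna().to_numpy(dtype=float)
            if len(v) == 0:
                continue
            rows.append(
                {
                    "group": group,
                    "variable": col,
                    "n": len(v),
                    "mean": float(np.mean(v)),
                    "q05": float(np.quantile(v, 0.05)),
                    "q95": float(np.quantile(v, 0.95)),
                    "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
                    "sd_defined": len(v) > 1,
                }
            )
    return pd.DataFrame(rows)


def pairwise_comparisons(
    table: pd.DataFrame,
    group_col: str = "group",
    value_cols: list[str] | None = None,
    statistics: tuple[str, ...] = ("mean", "median"),
    n_perm: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """All pairwise group permutation tests, Bonferroni corrected per battery.

    Returns a long-format frame (group1, group2, variable, statistic,
    observed_diff, p, p_bonferroni).  Seeds for individual tests are drawn
    from one generator seeded with ``seed``, so results are reproducible.
    """
    if value_cols is None:
        value_cols = [
            c
            for c in table.columns
            if c != group_col and pd.api.types.is_numeric_dtype(table[c])
        ]
    groups = sorted(table[group_col].dropna().unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for comparisons")
    rng = np.random.default_rng(seed)
    rows = []
    for g1, g2 in combinations(groups, 2):
        for col in value_cols:
            a = table.loc[table[group_col] == g1, col].dropna().to_numpy()
            b = table.loc[table[group_col] == g2, col].dropna().to_numpy()
            for stat in statistics:
                sub_seed = int(rng.integers(0, 2**31 - 1))
                res = perm_test(a, b, statistic=stat, n_perm=n_perm, seed=sub_seed)
                rows.append(
                    {
                        "group1": g1,
                        "group2": g2,
                        "variable": col,
                        "statistic": stat,
                        "observed_diff": res.observed_diff,
                        "p": res.p_empirical,
                    }
                )
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = bonferroni(out["p"].tolist())
    return out
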