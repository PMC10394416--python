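"""Nonparametric comparison battery for per-cell fit metrics.

The metrics produced by :func:`spinedyn.distfit.fit_condition` (r^2,
skewness, sigma_log, ...) are compared across experimental factors with
rank-based tests only, matching the skewed nature of the underlying
data: Mann-Whitney U between two independent groups (hemisphere or
genotype), Friedman's test across the three layers measured repeatedly
within each cell, and Kruskal-Wallis across cell ages.  Significant
omnibus tests are followed by pairwise post hocs with Bonferroni-Holm
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DataValidationError

ALPHA_DEFAULT = 0.05
#: use the exact Mann-Whitney null distribution up to this combined sample size
EXACT_MW_MAX_N = 20


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    groups: tuple
    n_per_group: tuple
    n_dropped: int = 0


@dataclass
class PosthocTable:
    """Pairwise comparisons with raw and Holm-adjusted p-values."""

    table: pd.DataFrame  # columns: pair, p_raw, p_holm, reject
    alpha: float = ALPHA_DEFAULT


def two_group_test(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact p-value when the combined sample is small and tie-free,
    otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise DataValidationError("each group needs n >= 3")
    pooled = np.concatenate([x, y])
    method = (
        "exact"
        if (x.size + y.size) <= EXACT_MW_MAX_N and np.unique(pooled).size == pooled.size
        else "asymptotic"
    )
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        "mann_whitney", float(res.statistic), float(res.pvalue),
        ("x", "y"), (x.size, y.size),
    )


def repeated_layers_test(matrix) -> TestResult:
    """Friedman chi-square over within-cell ranks (cells x conditions).

    Rows with missing entries are dropped and counted in ``n_dropped``.
    """
    m = np.asarray(pd.DataFrame(matrix), dtype=float)
    complete = ~np.isnan(m).any(axis=1)
    dropped = int((~complete).sum())
    m = m[complete]
    if m.shape[0] < 3 or m.shape[1] < 3:
        raise DataValidationError("need >= 3 complete cells and >= 3 conditions")
    if np.all(m == m[:, :1]):  # every row constant: no within-cell ranking possible
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.friedmanchisquare(*(m[:, j] for j in range(m.shape[1])))
    return TestResult(
        "friedman", float(stat), float(p),
        tuple(range(m.shape[1])), tuple([m.shape[0]] * m.shape[1]), dropped,
    )


def multi_age_test(groups) -> TestResult:
    """Kruskal-Wallis H with tie correction across >= 2 independent groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 3 for a in arrays):
        raise DataValidationError("need >= 2 groups with n >= 3 each")
    try:
        stat, p = stats.kruskal(*arrays)
    except ValueError:  # all values identical: statistic undefined
        stat, p = float("nan"), float("nan")
    return TestResult(
        "kruskal_wallis", float(stat), float(p),
        tuple(range(len(arrays))), tuple(a.size for a in arrays),
    )


def holm_adjust(p_values, alpha: float = ALPHA_DEFAULT, labels=None) -> PosthocTable:
    """Bonferroni-Holm step-down adjustment of a family of p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return PosthocTable(pd.DataFrame(columns=["pair", "p_raw", "p_holm", "reject"]), alpha)
    if ((p < 0) | (p > 1)).any():
        raise DataValidationError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    if labels is None:
        labels = [f"pair{i}" for i in range(p.size)]
    tab = pd.DataFrame(
        {"pair": list(labels), "p_raw": p, "p_holm": p_adj, "reject": reject}
    )
    return PosthocTable(tab, alpha)


@dataclass
class ComparisonReport:
    design: str
    metric: str
    omnibus: pd.DataFrame
    posthoc: pd.DataFrame = field(default_factory=pd.DataFrame)


def _paired_rank_sum(x, y) -> tuple[float, float]:
    d = np.asarray(x, float) - np.asarray(y, float)
    if np.all(d == 0):
        return 0.0, 1.0
    res = stats.wilcoxon(x, y)
    return float(res.statistic), float(res.pvalue)


def run_comparison_suite(
    metrics: pd.DataFrame,
    design: str,
    metric: str = "r2",
    alpha: float = ALPHA_DEFAULT,
) -> ComparisonReport:
    """Dispatch the appropriate test battery for one design factor.

    * ``hemisphere`` / ``group``: Mann-Whitney between the two
      ``side_or_group`` levels within each (layer, age) stratum.
    * ``layer``: Friedman over the three layers (repeated per cell) within
      each (age, side) stratum; post hoc paired rank-sum tests with Holm
      correction when the omnibus is significant.
    * ``age``: Kruskal-Wallis across ages within each (layer, side)
      stratum; post hoc Mann-Whitney pairs with Holm correction.

    ``metrics`` is the per-cell output of :func:`spinedyn.distfit.fit_condition`.
    """
    if metric not in metrics.columns:
        raise DataValidationError(f"metric column not found: {metric!r}")
    df = metrics.dropna(subset=[metric])
    if df.empty:
        raise DataValidationError(f"metric column is empty: {metric!r}")

    def strata(cols):
        cols = [c for c in cols if c in df.columns and df[c].notna().any()]
        if not cols:
            yield (), df
        else:
            yield from df.groupby(cols, dropna=False, observed=True, sort=True)

    omni_rows, post_rows = [], []

    if design in ("hemisphere", "group"):
        for key, grp in strata(["layer", "age"]):
            levels = sorted(grp["side_or_group"].dropna().unique())
            if len(levels) != 2:
                continue
            a = grp.loc[grp.side_or_group == levels[0], metric].to_numpy()
            b = grp.loc[grp.side_or_group == levels[1], metric].to_numpy()
            if a.size < 3 or b.size < 3:
                continue
            res = two_group_test(a, b)
            omni_rows.append(
                {"stratum": key, "test": res.test_name, "statistic": res.statistic,
                 "p_value": res.p_value, "n": (a.size, b.size),
                 "groups": tuple(levels)}
            )
    elif design == "layer":
        for key, grp in strata(["age", "side_or_group"]):
            wide = grp.pivot_table(index="cell_id", columns="layer", values=metric)
            if wide.shape[1] < 3:
                continue
            res = repeated_layers_test(wide)
            omni_rows.append(
                {"stratum": key, "test": res.test_name, "statistic": res.statistic,
                 "p_value": res.p_value, "n": res.n_per_group[0],
                 "groups": tuple(wide.columns)}
            )
            if np.isfinite(res.p_value) and res.p_value < alpha:
                complete = wide.dropna()
                pairs = list(combinations(wide.columns, 2))
                praw = []
                for la, lb in pairs:
                    _, p = _paired_rank_sum(complete[la], complete[lb])
                    praw.append(p)
                adj = holm_adjust(praw, alpha, labels=[f"{a}-{b}" for a, b in pairs])
                for _, r in adj.table.iterrows():
                    post_rows.append({"stratum": key, "test": "paired_rank_sum", **r})
    elif design == "age":
        for key, grp in strata(["layer", "side_or_group"]):
            ages = sorted(grp["age"].dropna().unique())
            samples = [grp.loc[grp.age == a, metric].to_numpy() for a in ages]
            if len(samples) < 2 or any(s.size < 3 for s in samples):
                continue
            res = multi_age_test(samples)
            omni_rows.append(
                {"stratum": key, "test": res.test_name, "statistic": res.statistic,
                 "p_value": res.p_value, "n": res.n_per_group, "groups": tuple(ages)}
            )
            if np.isfinite(res.p_value) and res.p_value < alpha:
                pairs = list(combinations(range(len(ages)), 2))
                praw = [two_group_test(samples[i], samples[j]).p_value for i, j in pairs]
                adj = holm_adjust(
                    praw, alpha, labels=[f"{ages[i]}-{ages[j]}" for i, j in pairs]
                )
                for _, r in adj.table.iterrows():
                    post_rows.append({"stratum": key, "test": "mann_whitney", **r})
    else:
        raise DataValidationError(f"unknown design {design!r}")

    return ComparisonReport(
        design=design,
        metric=metric,
        omnibus=pd.DataFrame(omni_rows),
        posthoc=pd.DataFrame(post_rows),
    )
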