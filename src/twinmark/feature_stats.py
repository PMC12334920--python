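"""Statistical validation of feature distributions between the two classes.

For every feature the two class-conditional samples (label 0: same person,
label 1: identical twins) are summarized by mean, sample SD and a 95%
t-distribution confidence interval, and compared with two two-sided tests:
Welch's unequal-variance t-test (Welch-Satterthwaite degrees of freedom) and
the Mann-Whitney U rank test (exact by enumeration for small tie-free
samples, otherwise the tie- and continuity-corrected normal approximation).
Features are ranked by the Welch p-value; p-values are reported raw, with an
optional Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import TooFewValues, ZeroVarianceBothGroups
from .pipeline import BOOKKEEPING_COLUMNS, FeatureTable

#: combined-sample bound under which the Mann-Whitney p is exact (no ties)
EXACT_MW_LIMIT = 12


@dataclass(frozen=True)
class ClassSummary:
    """Per-class descriptive statistics for one feature."""

    feature: str
    mean: dict[int, float]
    sd: dict[int, float]
    n: dict[int, int]
    ci_low: dict[int, float]
    ci_high: dict[int, float]


@dataclass(frozen=True)
class TestResult:
    feature: str
    t_stat: float
    t_df: float
    t_p: float
    u_stat: float
    u_p: float


def class_summary(values, labels, feature: str = "feature") -> ClassSummary:
    """Mean, sample SD (n-1) and 95% t-based CI per class."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=int)
    mean, sd, n, lo, hi = {}, {}, {}, {}, {}
    for c in (0, 1):
        x = v[y == c]
        if len(x) < 2:
            raise TooFewValues(f"class {c} has {len(x)} values; need >= 2")
        n[c] = int(len(x))
        mean[c] = float(x.mean())
        sd[c] = float(x.std(ddof=1))
        half = stats.t.ppf(0.975, n[c] - 1) * sd[c] / np.sqrt(n[c])
        lo[c], hi[c] = mean[c] - half, mean[c] + half
    return ClassSummary(feature=feature, mean=mean, sd=sd, n=n, ci_low=lo, ci_high=hi)


def welch_t(x0, x1) -> tuple[float, float, float]:
    """Welch's two-sided unequal-variance t-test: (t, df, p)."""
    a = np.asarray(x0, dtype=float)
    b = np.asarray(x1, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise TooFewValues("Welch's t-test needs >= 2 values per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ZeroVarianceBothGroups("both groups constant with different means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def mann_whitney(x0, x1) -> tuple[float, float]:
    """Two-sided Mann-Whitney U for group 0, midrank tie handling.

    Exact p by enumeration when n0+n1 <= 12 with no ties; otherwise normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(x0, dtype=float)
    b = np.asarray(x1, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise TooFewValues("Mann-Whitney needs >= 1 value per group")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    exact = (len(a) + len(b) <= EXACT_MW_LIMIT) and not has_ties
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic",
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj


def rank_features(table, top_k: int = 10, adjust: bool = False
                  ) -> list[tuple[str, ClassSummary, TestResult]]:
    """All features tested and sorted ascending by Welch p (top_k report).

    ``adjust=True`` replaces raw p-values with Benjamini-Hochberg adjusted
    ones before ranking.  ``top_k`` larger than the feature count returns the
    full list.
    """
    frame = table.frame if isinstance(table, FeatureTable) else table
    y = frame["label"].to_numpy(dtype=int)
    results = []
    for col in (c for c in frame.columns if c not in BOOKKEEPING_COLUMNS):
        v = frame[col].to_numpy(dtype=float)
        summ = class_summary(v, y, feature=col)
        try:
            t, df, tp = welch_t(v[y == 0], v[y == 1])
        except ZeroVarianceBothGroups:
            t, df, tp = float("inf"), float(len(v) - 2), 0.0
        u, up = mann_whitney(v[y == 0], v[y == 1])
        results.append((col, summ, TestResult(feature=col, t_stat=t, t_df=df,
                                              t_p=tp, u_stat=u, u_p=up)))
    if adjust:
        adj_t = benjamini_hochberg([r[2].t_p for r in results])
        adj_u = benjamini_hochberg([r[2].u_p for r in results])
        results = [
            (c, s, TestResult(feature=c, t_stat=r.t_stat, t_df=r.t_df,
                              t_p=float(pt), u_stat=r.u_stat, u_p=float(pu)))
            for (c, s, r), pt, pu in zip(results, adj_t, adj_u)
        ]
    results.sort(key=lambda item: (item[2].t_p, item[0]))
    return results[:top_k] if top_k else results


def report_frame(ranked) -> pd.DataFrame:
    """Tabular report mirroring the published schema: feature, per-class
    means (with n and CI), t-test p and Mann-Whitney p."""
    rows = []
    for feature, summ, test in ranked:
        rows.append({
            "feature": feature,
            "mean_0": summ.mean[0], "mean_1": summ.mean[1],
            "sd_0": summ.sd[0], "sd_1": summ.sd[1],
            "n_0": summ.n[0], "n_1": summ.n[1],
            "ci_low_0": summ.ci_low[0], "ci_high_0": summ.ci_high[0],
            "ci_low_1": summ.ci_low[1], "ci_high_1": summ.ci_high[1],
            "t_p": test.t_p, "mw_p": test.u_p,
        })
    return pd.DataFrame(rows)


def boxplot_frame(table, features) -> pd.DataFrame:
    """Tidy (feature, label, value) export for box plotting."""
    frame = table.frame if isinstance(table, FeatureTable) else table
    rows = []
    for feature in features:
        for label, value in zip(frame["label"], frame[feature]):
            rows.append({"feature": feature, "label": int(label), "value": float(value)})
    return pd.DataFrame(rows)
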