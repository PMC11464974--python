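"""Questionnaire analysis: one-way ANOVA and Tukey HSD across stimulation levels.

Responses (subjective pain score SPS 0-5, SAM valence/arousal 1-9) are
compared across the five stimulation levels with a plain one-way ANOVA and
Tukey's honestly-significant-difference post hoc test at alpha = 0.05.

Statistical caveat: each subject rates every level, so observations are
repeated measures; like much of the applied literature, the default analysis
ignores that structure and treats levels as independent groups, which is
anticonservative for within-subject designs.  Interpret significance
accordingly.

For unbalanced groups the Tukey statistic uses the harmonic-mean sample size
(the Tukey-Kramer convention written as a single n):

    Q_ij = |mean_i - mean_j| / sqrt(MSW / n_h),   n_h = k / sum(1/n_i)

with significance judged against the studentized-range distribution on
(k, N - k).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AnovaResult", "TukeyResult", "anova_oneway", "tukey_hsd"]


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass
class TukeyResult:
    """Pairwise Tukey comparisons; one row per unordered group pair."""

    table: pd.DataFrame          # columns: group_a, group_b, mean_diff, q, p, significant
    alpha: float
    q_critical: float

    def q(self, a, b) -> float:
        t = self.table
        row = t[((t.group_a == a) & (t.group_b == b)) | ((t.group_a == b) & (t.group_b == a))]
        if row.empty:
            raise KeyError(f"no comparison for groups {a!r}, {b!r}")
        return float(row["q"].iloc[0])


def _groups(table: pd.DataFrame, response: str, factor: str) -> list[np.ndarray]:
    levels = sorted(table[factor].unique())
    groups = [table.loc[table[factor] == lv, response].to_numpy(dtype=float) for lv in levels]
    if len(groups) < 2:
        raise ValueError("need at least two factor levels")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least two observations")
    if all(np.ptp(g) == 0 for g in groups):
        raise ValueError("zero within-group variance everywhere; F is undefined")
    return groups


def anova_oneway(table: pd.DataFrame, response: str, factor: str = "level") -> AnovaResult:
    """Classical one-way fixed-effects ANOVA of ``response`` across ``factor``."""
    groups = _groups(table, response, factor)
    res = stats.f_oneway(*groups)
    k = len(groups)
    n_tot = sum(len(g) for g in groups)
    return AnovaResult(F=float(res.statistic), df_between=k - 1,
                       df_within=n_tot - k, p=float(res.pvalue))


def tukey_hsd(table: pd.DataFrame, response: str, factor: str = "level",
              alpha: float = 0.05) -> TukeyResult:
    """Tukey HSD post hoc over all factor-level pairs (harmonic-n for unbalance)."""
    groups = _groups(table, response, factor)
    levels = sorted(table[factor].unique())
    k = len(groups)
    n_tot = sum(len(g) for g in groups)
    df_w = n_tot - k
    msw = sum(((g - g.mean())**2).sum() for g in groups) / df_w
    n_h = k / sum(1.0 / len(g) for g in groups)
    se = np.sqrt(msw / n_h)
    q_crit = float(stats.studentized_range.ppf(1 - alpha, k, df_w))
    rows = []
    for (i, a), (j, b) in combinations(enumerate(levels), 2):
        diff = groups[j].mean() - groups[i].mean()
        q = abs(diff) / se
        p = float(stats.studentized_range.sf(q, k, df_w))
        rows.append({"group_a": a, "group_b": b, "mean_diff": float(diff),
                     "q": float(q), "p": p, "significant": bool(q > q_crit)})
    return TukeyResult(table=pd.DataFrame(rows), alpha=alpha, q_critical=q_crit)
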