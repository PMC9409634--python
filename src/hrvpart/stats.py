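"""Group-comparison statistics for the three-group cohort.

The decision tree mirrors standard clinical-statistics practice:
an Anderson-Darling gate (5% level, parameters estimated) decides
normality per group; a variable is summarized and tested parametrically
only when every group passes.  Omnibus comparison is one-way ANOVA
(normal), Kruskal-Wallis (non-normal) or Pearson chi-square without
continuity correction (categorical).  Post hoc pairwise tests use the
matching two-sample test with a Bonferroni per-comparison threshold of
0.05/3 (reported as 0.017); significance flags are only populated when
the omnibus p is below 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ParameterError

__all__ = [
    "BONFERRONI_THRESHOLD",
    "GroupComparisonRow",
    "normality",
    "omnibus",
    "posthoc",
    "summarize",
    "group_comparison_table",
]

#: per-comparison significance level for the three pairwise contrasts
BONFERRONI_THRESHOLD = round(0.05 / 3, 3)  # 0.017
_PAIR_ALPHA = 0.05 / 3
MIN_GROUP_N = 8


@dataclass
class GroupComparisonRow:
    variable: str
    summaries: dict  # group -> formatted summary string
    group_n: dict  # group -> n with data
    omnibus_p: float
    test: str
    normal: bool
    pairwise_p: dict = field(default_factory=dict)  # "A|B" -> p
    pairwise_flags: dict = field(default_factory=dict)  # "A|B" -> bool


def normality(groups: dict | list, min_n: int = MIN_GROUP_N) -> tuple[bool, list[bool | None]]:
    """Anderson-Darling normality gate.

    Returns ``(all_normal, per_group)``; a group with fewer than
    ``min_n`` observations is inconclusive (``None``) and the variable
    is treated as non-normal.
    """
    values = groups.values() if isinstance(groups, dict) else groups
    per_group: list[bool | None] = []
    for g in values:
        g = _dropna(g)
        if len(g) < min_n or np.std(g) == 0:
            per_group.append(None)
            continue
        res = sps.anderson(g, dist="norm")
        crit_5pct = res.critical_values[list(res.significance_level).index(5.0)]
        per_group.append(bool(res.statistic < crit_5pct))
    all_normal = all(p is True for p in per_group) and len(per_group) > 0
    return all_normal, per_group


def omnibus(
    groups: dict | list, kind: str = "continuous", normal: bool | None = None
) -> tuple[float, str]:
    """Omnibus p-value across groups and the name of the test used.

    ``kind='categorical'`` expects per-group 0/1 (or category) vectors
    and applies Pearson chi-square without continuity correction.
    Degenerate inputs (all values identical) report p = 1.
    """
    values = [np.asarray(_dropna(g)) for g in
              (groups.values() if isinstance(groups, dict) else groups)]
    nonempty = [g for g in values if len(g) > 0]
    if len(nonempty) < len(values):
        warnings.warn("omnibus: empty group excluded", stacklevel=2)
    if len(nonempty) < 2:
        raise ParameterError("omnibus needs >= 2 non-empty groups")

    if kind == "categorical":
        cats = np.unique(np.concatenate(nonempty))
        table = np.array([[np.sum(g == c) for c in cats] for g in nonempty]).T
        table = table[table.sum(axis=1) > 0]
        if table.shape[0] < 2:
            return 1.0, "chi-square (degenerate)"
        chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
        return float(p), "chi-square"

    pooled = np.concatenate(nonempty)
    if np.all(pooled == pooled[0]):
        return 1.0, "degenerate (all equal)"
    if normal is None:
        normal, _ = normality(nonempty)
    if normal:
        stat, p = sps.f_oneway(*nonempty)
        return float(p), "ANOVA"
    stat, p = sps.kruskal(*nonempty)
    return float(p), "Kruskal-Wallis"


def chi_square_counts(successes, totals) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on success/total counts.

    Convenience for published contingency rows given as "k of n" per
    group; returns ``(chi2, p)``.
    """
    successes = np.asarray(successes, dtype=float)
    totals = np.asarray(totals, dtype=float)
    table = np.vstack([successes, totals - successes])
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def posthoc(
    groups: dict,
    kind: str = "continuous",
    normal: bool | None = None,
    omnibus_p: float | None = None,
) -> tuple[dict, dict]:
    """All pairwise tests with Bonferroni-thresholded flags.

    The pairwise test matches the variable type: Student's t (normal),
    Mann-Whitney (non-normal) or chi-square (categorical).  Flags are
    ``p < 0.05/3`` and are forced False when the omnibus p (if given)
    is >= 0.05.
    """
    names = list(groups)
    data = {k: np.asarray(_dropna(v)) for k, v in groups.items()}
    if normal is None and kind != "categorical":
        normal, _ = normality(list(data.values()))
    pvals: dict = {}
    flags: dict = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = data[names[i]], data[names[j]]
            key = f"{names[i]}|{names[j]}"
            pvals[key] = _pairwise_p(a, b, kind, bool(normal))
            gated = omnibus_p is not None and not (omnibus_p < 0.05)
            flags[key] = bool(pvals[key] < _PAIR_ALPHA) and not gated
    return pvals, flags


def _pairwise_p(a, b, kind: str, normal: bool) -> float:
    if len(a) == 0 or len(b) == 0:
        return float("nan")
    if kind == "categorical":
        cats = np.unique(np.concatenate([a, b]))
        if len(cats) < 2:
            return 1.0
        table = np.array([[np.sum(g == c) for c in cats] for g in (a, b)]).T
        table = table[table.sum(axis=1) > 0]
        if table.shape[0] < 2:
            return 1.0
        return float(sps.chi2_contingency(table, correction=False)[1])
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return 1.0
    if normal:
        return float(sps.ttest_ind(a, b).pvalue)
    return float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def summarize(values, normal: bool, kind: str = "continuous", decimals: int = 1) -> str:
    """Format one group's values the way clinical tables print them.

    mean ± SD (normal), median (p25, p75) with linear-interpolation
    percentiles (non-normal), or count (percent) for 0/1 data.
    """
    v = np.asarray(_dropna(values), dtype=float)
    if len(v) == 0:
        return "-"
    if kind == "categorical":
        k = int(np.sum(v == 1))
        return f"{k} ({round(100 * k / len(v)):.0f}%)"
    if normal:
        sd = np.std(v, ddof=1) if len(v) > 1 else 0.0
        return f"{np.mean(v):.{decimals}f} ± {sd:.{decimals}f}"
    med = np.percentile(v, 50)
    p25 = np.percentile(v, 25)
    p75 = np.percentile(v, 75)
    return f"{med:.{decimals}f} ({p25:.{decimals}f}, {p75:.{decimals}f})"


def group_comparison_table(
    df: pd.DataFrame,
    variables: list[str],
    group_col: str = "group",
    categorical: set | None = None,
    group_order: list[str] | None = None,
) -> list[GroupComparisonRow]:
    """Tables 1-4-shaped comparison: one row per variable."""
    categorical = categorical or set()
    order = group_order or list(pd.unique(df[group_col]))
    rows = []
    for var in variables:
        if var not in df.columns:
            warnings.warn(f"variable {var!r} not in cohort; skipped", stacklevel=2)
            continue
        groups = {g: _dropna(df.loc[df[group_col] == g, var]) for g in order}
        kind = "categorical" if var in categorical else "continuous"
        if kind == "categorical":
            normal = False
        else:
            normal, _ = normality(list(groups.values()))
        p, test = omnibus(groups, kind=kind, normal=normal)
        pv, fl = posthoc(groups, kind=kind, normal=normal, omnibus_p=p)
        rows.append(
            GroupComparisonRow(
                variable=var,
                summaries={g: summarize(v, normal, kind) for g, v in groups.items()},
                group_n={g: int(len(v)) for g, v in groups.items()},
                omnibus_p=p,
                test=test,
                normal=normal,
                pairwise_p=pv,
                pairwise_flags=fl,
            )
        )
    return rows


def _dropna(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return v[~np.isnan(v)]
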