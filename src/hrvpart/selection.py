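"""Per-category stepwise pre-selection of predictors.

Before partitioning, each Δ index is regressed on each variable
category separately with bidirectional stepwise OLS (start empty; add
the candidate with the smallest partial-F p when <= p_enter = 0.05;
after each addition drop any included variable whose p rises above
p_remove = 0.10; iterate to a fixed point).  Ties break on (p, name) so
the procedure is fully deterministic.  The union of per-category
selections, in a stable category-then-name order, feeds the
partitioner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ParameterError

__all__ = [
    "CATEGORIES",
    "CATEGORY_ORDER",
    "StepwiseSelection",
    "stepwise",
    "assemble_predictors",
]

#: variable taxonomy: category -> cohort columns
CATEGORIES: dict[str, list[str]] = {
    "valve": ["vmax", "pgmean", "pgmax", "ava", "avai"],
    "ventricular": ["lvef", "lvm", "lvmi", "rwt"],
    "biochemical": ["glucose", "cholesterol", "triglycerides", "hemoglobin", "albumin"],
    "anthropometric_clinical": [
        "age", "bmi", "sbp", "dbp", "female", "medication",
        "smoking", "hypertension", "diabetes",
    ],
    "mbf": ["mbf"],
    "inflammatory": ["crp", "et1", "il4", "ifng", "timp1", "mmp2_timp1"],
    "d_mean_nn": ["d_mean_nn"],
}
CATEGORY_ORDER = list(CATEGORIES)

MAX_COMBINED = 12


@dataclass
class StepwiseSelection:
    dependent: str
    category: str
    selected: list[str]
    log: list[tuple[str, str, float]] = field(default_factory=list)  # (var, action, p)
    n: int = 0


def stepwise(
    y,
    X: pd.DataFrame,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    dependent: str = "y",
    category: str = "",
    min_n_margin: int = 10,
) -> StepwiseSelection:
    """Bidirectional stepwise OLS selection within one category.

    Complete cases over y and all candidates.  When n < margin + k the
    candidate set is reduced to the best univariate predictors that fit
    the budget (with a warning).  Zero-variance candidates are dropped.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"x{j}" for j in range(X.shape[1])]
    data = X.copy()
    data["_y"] = np.asarray(y, dtype=float)
    data = data.dropna()
    yv = data.pop("_y").to_numpy()
    n = len(yv)
    log: list[tuple[str, str, float]] = []

    candidates = []
    for c in X.columns:
        if np.std(data[c].to_numpy()) == 0:
            warnings.warn(f"stepwise: zero-variance candidate {c!r} dropped", stacklevel=2)
            log.append((c, "dropped-zero-variance", float("nan")))
        else:
            candidates.append(c)

    if np.std(yv) == 0 or n < 3:
        return StepwiseSelection(dependent, category, [], log, n)

    if n < min_n_margin + len(candidates):
        budget = max(0, n - min_n_margin)
        warnings.warn(
            f"stepwise[{dependent}/{category}]: n={n} too small for "
            f"{len(candidates)} candidates; reduced to {budget} by univariate p",
            stacklevel=2,
        )
        uni = sorted(candidates, key=lambda c: (_add_p(yv, data, [], c), c))
        candidates = sorted(uni[:budget])

    selected: list[str] = []
    while True:
        changed = False
        remaining = [c for c in candidates if c not in selected]
        if remaining:
            entry = sorted(
                ((_add_p(yv, data, selected, c), c) for c in remaining)
            )[0]
            if entry[0] <= p_enter:
                selected.append(entry[1])
                log.append((entry[1], "add", float(entry[0])))
                changed = True
        # backward pass: remove the worst offender until all p <= p_remove
        while len(selected) > 0:
            pvals = _included_p(yv, data, selected)
            worst = sorted(((p, c) for c, p in pvals.items()), reverse=True)[0]
            if worst[0] > p_remove:
                selected.remove(worst[1])
                log.append((worst[1], "remove", float(worst[0])))
                changed = True
            else:
                break
        if not changed:
            break
    return StepwiseSelection(dependent, category, selected, log, n)


def _add_p(yv, data, selected, candidate) -> float:
    """Partial-F p-value of `candidate` when added to the current model."""
    cols = selected + [candidate]
    Xm = sm.add_constant(data[cols].to_numpy(float))
    try:
        fit = sm.OLS(yv, Xm).fit()
    except Exception:
        return float("inf")
    p = fit.pvalues[-1]
    return float(p) if np.isfinite(p) else float("inf")


def _included_p(yv, data, selected) -> dict[str, float]:
    Xm = sm.add_constant(data[selected].to_numpy(float))
    fit = sm.OLS(yv, Xm).fit()
    return {c: float(fit.pvalues[i + 1]) for i, c in enumerate(selected)}


def stepwise_by_category(
    cohort: pd.DataFrame,
    delta: str,
    categories: dict[str, list[str]] | None = None,
    **kwargs,
) -> list[StepwiseSelection]:
    """Run the per-category pre-selection for one Δ index.

    A category is skipped when the dependent variable itself belongs to
    it (ΔmeanNN is not a covariable of its own model) or when none of
    its columns are present.
    """
    categories = categories or CATEGORIES
    out = []
    for cat, cols in categories.items():
        cols = [c for c in cols if c in cohort.columns and c != delta]
        if delta in CATEGORIES.get(cat, []) and cat == "d_mean_nn":
            continue
        if not cols:
            continue
        sub = cohort[[delta] + cols].copy()
        sel = stepwise(
            sub[delta], sub[cols], dependent=delta, category=cat, **kwargs
        )
        out.append(sel)
    return out


def assemble_predictors(
    selections: list[StepwiseSelection],
    category_order: list[str] | None = None,
    max_combined: int = MAX_COMBINED,
) -> list[str]:
    """Union of per-category selections in stable (category, name) order."""
    if not selections:
        raise ParameterError("no selections to assemble")
    order = category_order or CATEGORY_ORDER
    ranked = sorted(
        selections,
        key=lambda s: order.index(s.category) if s.category in order else len(order),
    )
    combined: list[str] = []
    for sel in ranked:
        for name in sorted(sel.selected):
            if name not in combined:
                combined.append(name)
    if len(combined) > max_combined:
        raise ParameterError(
            f"{len(combined)} combined predictors exceed the 2^k budget "
            f"(max {max_combined})"
        )
    return combined
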