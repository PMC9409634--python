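"""Hierarchical partitioning of regression R².

Decomposes the R² of an ordinary-least-squares model into each
predictor's independent contribution I_j and joint contribution J_j.
I_j is the average improvement in R² from adding predictor j across all
2^(k-1) submodels that exclude it, weighted by Shapley coefficients

    I_j = sum over S not containing j of  |S|! (k-|S|-1)! / k! * [R²(S ∪ {j}) - R²(S)]

which equals the Chevan-Sutherland average over hierarchy levels and
the average marginal gain over all k! predictor orderings (both are
provided as independent cross-check routines).  J_j = R²({j}) - I_j is
the part of predictor j's univariate R² shared with the others, and
sum_j I_j equals the full-model R² exactly.

Subset R² values are computed from centered cross-product moments (one
pass over the data, then one small solve per subset), which is
algebraically identical to refitting OLS per subset.  Negative I values
(suppressor configurations) are reported as-is.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = [
    "PartitionResult",
    "all_subsets_r2",
    "partition",
    "partition_by_levels",
    "partition_by_orderings",
    "partition_with_repeats",
    "partition_cohort",
]

MAX_PREDICTORS = 12


@dataclass
class PartitionResult:
    names: list[str]
    independent: np.ndarray  # I_j, variance fractions
    joint: np.ndarray  # J_j = univariate R² - I_j
    r2_full: float
    n: int
    repeats: int = 1

    @property
    def i_pct_absolute(self) -> np.ndarray:
        """100 * I_j: share of total outcome variance."""
        return 100.0 * self.independent

    @property
    def i_pct_of_r2(self) -> np.ndarray:
        """100 * I_j / sum(I): share of the explained variance."""
        total = self.independent.sum()
        return 100.0 * self.independent / total if total != 0 else np.full_like(
            self.independent, np.nan
        )

    def as_dict(self) -> dict:
        return {
            "names": list(self.names),
            "independent": self.independent.tolist(),
            "joint": self.joint.tolist(),
            "i_pct_absolute": self.i_pct_absolute.tolist(),
            "i_pct_of_r2": self.i_pct_of_r2.tolist(),
            "r2_full": self.r2_full,
            "n": self.n,
            "repeats": self.repeats,
        }


def _moments(y: np.ndarray, X: np.ndarray):
    yc = y - y.mean()
    Xc = X - X.mean(axis=0)
    return Xc.T @ Xc, Xc.T @ yc, float(yc @ yc)


def _subset_r2_from_moments(G, g, syy, mask_bits: tuple[int, ...]) -> float:
    if not mask_bits:
        return 0.0
    idx = list(mask_bits)
    Gs = G[np.ix_(idx, idx)]
    gs = g[idx]
    try:
        beta = np.linalg.solve(Gs, gs)
    except np.linalg.LinAlgError:
        warnings.warn("singular design for a subset; using pseudoinverse", stacklevel=3)
        beta = np.linalg.pinv(Gs) @ gs
    if syy == 0:
        return 0.0
    return float(gs @ beta / syy)


def _subsets_r2_from_moments(G, g, syy, k: int) -> dict[frozenset, float]:
    out: dict[frozenset, float] = {}
    for r in range(k + 1):
        for combo in itertools.combinations(range(k), r):
            out[frozenset(combo)] = _subset_r2_from_moments(G, g, syy, combo)
    return out


def all_subsets_r2(y, X) -> dict[frozenset, float]:
    """OLS R² for every predictor subset (intercept always included).

    Keys are frozensets of column indices; the empty set maps to 0.
    Complete cases only; k is capped at 12 (4096 fits).
    """
    y, X, _ = _as_arrays(y, X)
    n, k = X.shape
    if k > MAX_PREDICTORS:
        raise ParameterError(f"at most {MAX_PREDICTORS} predictors (got {k})")
    if n <= k + 2:
        raise ParameterError(f"need n > k + 2 complete cases (n={n}, k={k})")
    G, g, syy = _moments(y, X)
    return _subsets_r2_from_moments(G, g, syy, k)


def _decompose(r2: dict[frozenset, float], k: int) -> tuple[np.ndarray, np.ndarray]:
    fact = [math.factorial(i) for i in range(k + 1)]
    independent = np.zeros(k)
    for j in range(k):
        acc = 0.0
        for subset, r2_s in r2.items():
            if j in subset:
                continue
            s = len(subset)
            w = fact[s] * fact[k - s - 1] / fact[k]
            acc += w * (r2[subset | {j}] - r2_s)
        independent[j] = acc
    joint = np.array([r2[frozenset({j})] - independent[j] for j in range(k)])
    return independent, joint


def partition_from_moments(
    G: np.ndarray, g: np.ndarray, syy: float, names: list[str], n: int
) -> PartitionResult:
    """Decomposition directly from centered cross-product moments.

    Lets callers work on analytically adjusted moments (e.g. adding a
    known noise variance to the outcome sum of squares).
    """
    k = len(g)
    if k > MAX_PREDICTORS:
        raise ParameterError(f"at most {MAX_PREDICTORS} predictors (got {k})")
    r2 = _subsets_r2_from_moments(G, g, syy, k)
    independent, joint = _decompose(r2, k)
    return PartitionResult(list(names), independent, joint, r2[frozenset(range(k))], n)


def partition(y, X, names: list[str] | None = None) -> PartitionResult:
    """Shapley/hierarchical decomposition of the full-model R²."""
    y, X, names = _as_arrays(y, X, names)
    n, k = X.shape
    r2 = all_subsets_r2(y, X)
    independent, joint = _decompose(r2, k)
    return PartitionResult(names, independent, joint, r2[frozenset(range(k))], n)


def partition_by_levels(y, X, names: list[str] | None = None) -> PartitionResult:
    """Chevan-Sutherland level averaging (independent cross-check).

    For each hierarchy level h, average the marginal R² gain of adding
    predictor j over all size-h subsets that exclude it; I_j is the mean
    over levels h = 0..k-1.
    """
    y, X, names = _as_arrays(y, X, names)
    n, k = X.shape
    r2 = all_subsets_r2(y, X)
    independent = np.zeros(k)
    for j in range(k):
        level_means = []
        for h in range(k):
            gains = [
                r2[subset | {j}] - r2_s
                for subset, r2_s in r2.items()
                if len(subset) == h and j not in subset
            ]
            level_means.append(np.mean(gains))
        independent[j] = np.mean(level_means)
    joint = np.array([r2[frozenset({j})] - independent[j] for j in range(k)])
    return PartitionResult(names, independent, joint, r2[frozenset(range(k))], n)


def partition_by_orderings(y, X, names: list[str] | None = None) -> PartitionResult:
    """Brute-force average of marginal gains over all k! orderings.

    The literal Shapley definition; exponential in k, intended as an
    oracle for k <= 8.
    """
    y, X, names = _as_arrays(y, X, names)
    n, k = X.shape
    if k > 8:
        raise ParameterError("ordering oracle limited to k <= 8")
    r2 = all_subsets_r2(y, X)
    independent = np.zeros(k)
    n_orders = math.factorial(k)
    for order in itertools.permutations(range(k)):
        seen: frozenset = frozenset()
        for j in order:
            independent[j] += r2[seen | {j}] - r2[seen]
            seen = seen | {j}
    independent /= n_orders
    joint = np.array([r2[frozenset({j})] - independent[j] for j in range(k)])
    return PartitionResult(names, independent, joint, r2[frozenset(range(k))], n)


def partition_with_repeats(
    y, X, names: list[str] | None = None, repeats: int = 10, seed: int | None = None
) -> PartitionResult:
    """Average the decomposition over random predictor orderings.

    Reproduces the repeat-and-average protocol used with
    order-sensitive partitioning software for k > 9.  The closed-form
    decomposition is order-invariant, so every repeat returns the same
    values; the averaging is kept for procedural fidelity and audit.
    """
    y, X, names = _as_arrays(y, X, names)
    n, k = X.shape
    rng = np.random.default_rng(seed)
    acc_i = np.zeros(k)
    acc_j = np.zeros(k)
    r2_full = 0.0
    for _ in range(repeats):
        perm = rng.permutation(k)
        res = partition(y, X[:, perm], [names[p] for p in perm])
        inv = np.argsort(perm)
        acc_i += res.independent[inv]
        acc_j += res.joint[inv]
        r2_full = res.r2_full
    return PartitionResult(names, acc_i / repeats, acc_j / repeats, r2_full, n, repeats)


def partition_cohort(
    cohort: pd.DataFrame,
    delta: str,
    predictors: list[str],
    valve_parameters: tuple = ("vmax", "pgmean", "pgmax", "ava", "avai"),
    repeats: int = 10,
    seed: int | None = None,
    auto_repeat_threshold: int = 9,
) -> dict:
    """One summary-table row for one Δ index.

    Runs the decomposition on complete cases of ``delta ~ predictors``
    and reports the valve parameter's independent contribution in both
    percentage conventions, the covariable list, and the full-model R².
    The repeat-averaging protocol engages automatically for k > 9.
    """
    missing = [p for p in predictors if p not in cohort.columns]
    if missing or delta not in cohort.columns:
        raise ParameterError(f"columns not in cohort: {missing + [delta] if delta not in cohort.columns else missing}")
    sub = cohort[[delta] + list(predictors)].dropna()
    y = sub[delta].to_numpy(float)
    X = sub[list(predictors)].to_numpy(float)
    k = X.shape[1]
    if k > auto_repeat_threshold:
        res = partition_with_repeats(y, X, list(predictors), repeats=repeats, seed=seed)
    else:
        res = partition(y, X, list(predictors))
    valve = [p for p in predictors if p in valve_parameters]
    row = {
        "delta": delta,
        "valve_parameter": valve[0] if valve else None,
        "covariables": [p for p in predictors if p not in valve_parameters],
        "r2_combined": res.r2_full,
        "n": res.n,
        "repeats": res.repeats,
    }
    if valve:
        j = list(predictors).index(valve[0])
        row["valve_i_pct_absolute"] = float(res.i_pct_absolute[j])
        row["valve_i_pct_of_r2"] = float(res.i_pct_of_r2[j])
    else:
        row["valve_i_pct_absolute"] = None
        row["valve_i_pct_of_r2"] = None
    row["partition"] = res.as_dict()
    return row


def _as_arrays(y, X, names: list[str] | None = None):
    if isinstance(X, pd.DataFrame):
        names = names or list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != len(X):
        raise ParameterError("y and X must have the same number of rows")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    return y, X, names
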