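"""Cohort statistics: group comparison and discriminant classification.

Given a per-subject metrics table with a two-level group label
(control vs diabetic neuropathy), this module provides

* descriptive statistics (mean, sample SD),
* a normality-driven two-sample test dispatcher: Welch's t-test when
  both groups look normal under a Lilliefors-type Kolmogorov–Smirnov
  check, Mann–Whitney U otherwise,
* Welch's t-test computed directly from printed summary statistics
  (mean, SD, n per group), useful when only published tables are
  available,
* stepwise linear discriminant analysis driven by Wilks' Λ with
  partial-F entry/removal, equal priors and resubstitution (or
  leave-one-out) classification accuracy,
* a seeded cohort simulator drawing subjects from per-group
  per-variable (mean, SD) summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.diagnostic import lilliefors

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_NORMALITY = 0.05
DEFAULT_P_ENTER = 0.05
DEFAULT_P_REMOVE = 0.10


@dataclass
class TestResult:
    variable: str
    test_used: str  # "t_welch" or "mann_whitney"
    statistic: float
    p_value: float
    df: float | None = None
    note: str | None = None


@dataclass
class DiscriminantResult:
    selected_variables: list[str]
    wilks_lambda: float
    p_value: float
    confusion: np.ndarray  # rows: true group, cols: predicted
    accuracy_overall: float  # percent
    accuracy_per_group: dict[str, float] = field(default_factory=dict)
    group_order: list[str] = field(default_factory=list)


def describe(values) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n−1 denominator)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("describe requires at least two values")
    return float(x.mean()), float(x.std(ddof=1))


def _is_normalish(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:
        return True  # degenerate constant sample; KS undefined
    _, p = lilliefors(x, dist="norm")
    return p > alpha


def dispatch_test(
    group_a,
    group_b,
    alpha_normality: float = DEFAULT_ALPHA_NORMALITY,
    variable: str = "",
) -> TestResult:
    """Two-sample comparison with normality-driven test choice.

    Both groups are screened with a Kolmogorov–Smirnov normality test
    (Lilliefors variant: the normal parameters are estimated from the
    sample).  If both pass at ``alpha_normality``, Welch's unequal-
    variance t-test is used; otherwise the Mann–Whitney U test
    (exact for small untied samples, normal approximation with tie
    correction otherwise).  Two-sided p-values throughout.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if np.array_equal(np.sort(a), np.sort(b)) and np.ptp(a) == 0:
        logger.info("degenerate identical constant groups for %s; p = 1", variable or "<var>")
        return TestResult(variable=variable, test_used="t_welch", statistic=0.0,
                          p_value=1.0, df=float(a.size + b.size - 2), note="degenerate")
    if _is_normalish(a, alpha_normality) and _is_normalish(b, alpha_normality):
        t, p = sps.ttest_ind(a, b, equal_var=False)
        # Welch–Satterthwaite degrees of freedom
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        return TestResult(variable=variable, test_used="t_welch",
                          statistic=float(t), p_value=float(p), df=float(df),
                          note="normality accepted (Lilliefors KS)")
    exact = a.size <= 8 and b.size <= 8 and np.unique(np.concatenate([a, b])).size == a.size + b.size
    u, p = sps.mannwhitneyu(a, b, alternative="two-sided",
                            method="exact" if exact else "asymptotic")
    return TestResult(variable=variable, test_used="mann_whitney",
                      statistic=float(u), p_value=float(p),
                      note="normality rejected (Lilliefors KS)")


def welch_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variable: str = "",
) -> TestResult:
    """Welch's t-test from group summary statistics.

    ``t = (m₁−m₂)/√(s₁²/n₁ + s₂²/n₂)`` with Welch–Satterthwaite
    degrees of freedom and a two-sided p-value; lets published
    mean ± SD tables be re-tested without raw data.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be at least 2")
    t, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TestResult(variable=variable, test_used="t_welch",
                      statistic=float(t), p_value=float(p), df=float(df))


def compare_groups(
    table: pd.DataFrame,
    group_col: str = "group",
    variables: list[str] | None = None,
    alpha_normality: float = DEFAULT_ALPHA_NORMALITY,
) -> list[TestResult]:
    """Run the dispatching two-sample test on every metric column."""
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, found {groups}")
    if variables is None:
        variables = [c for c in table.columns
                     if c != group_col and pd.api.types.is_numeric_dtype(table[c])]
    a = table[table[group_col] == groups[0]]
    b = table[table[group_col] == groups[1]]
    return [dispatch_test(a[v], b[v], alpha_normality, variable=v) for v in variables]


# ---------------------------------------------------------------------------
# Wilks'-lambda stepwise discriminant analysis


def wilks_lambda(X: np.ndarray, y: np.ndarray) -> float:
    """Wilks' Λ = det(W)/det(T) for the variable set in X.

    W is the pooled within-group cross-product matrix and T the total
    one; for a single variable this reduces to SS_within / SS_total.
    Λ near 0 means the groups are well separated; Λ = 1 means the
    variables carry no group information.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    grand = X.mean(axis=0)
    T = (X - grand).T @ (X - grand)
    W = np.zeros_like(T)
    for g in np.unique(y):
        Xg = X[y == g]
        W += (Xg - Xg.mean(axis=0)).T @ (Xg - Xg.mean(axis=0))
    detT = np.linalg.det(T)
    if detT == 0:
        return 1.0
    return float(np.linalg.det(W) / detT)


def _partial_f_p(lmbda_small: float, lmbda_big: float, n: int, n_groups: int, p_in: int) -> float:
    """p-value of the partial F for adding one variable.

    ``lmbda_small`` is Λ of the model without the candidate (p_in
    variables), ``lmbda_big`` with it.  F has (g−1, n−g−p_in) df.
    """
    df2 = n - n_groups - p_in
    if df2 <= 0 or lmbda_big <= 0:
        return 1.0
    f = (lmbda_small / lmbda_big - 1.0) * df2 / (n_groups - 1)
    return float(sps.f.sf(max(f, 0.0), n_groups - 1, df2))


def stepwise_lda(
    table: pd.DataFrame,
    group_col: str = "group",
    variables: list[str] | None = None,
    p_enter: float = DEFAULT_P_ENTER,
    p_remove: float = DEFAULT_P_REMOVE,
    leave_one_out: bool = False,
) -> DiscriminantResult:
    """Stepwise linear discriminant classification of a two-group cohort.

    Forward selection with backward removal: at each step the variable
    minimising Wilks' Λ enters if its partial-F p-value is below
    ``p_enter``; any selected variable whose removal p-value exceeds
    ``p_remove`` is dropped.  The final discriminant is fitted with
    equal prior probabilities and scored by resubstitution (or
    leave-one-out when requested).  With no admissible variable the
    result falls back to majority-class assignment.
    """
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, found {groups}")
    if variables is None:
        variables = [c for c in table.columns
                     if c != group_col and pd.api.types.is_numeric_dtype(table[c])]
    if len(variables) < 1:
        raise ValueError("at least one candidate variable is required")
    y = table[group_col].to_numpy()
    n = len(table)

    selected: list[str] = []
    while True:
        changed = False
        # entry step
        best_var, best_lmbda = None, None
        lmbda_cur = wilks_lambda(table[selected].to_numpy(), y) if selected else 1.0
        for v in variables:
            if v in selected:
                continue
            lm = wilks_lambda(table[selected + [v]].to_numpy(), y)
            if best_lmbda is None or lm < best_lmbda:
                best_var, best_lmbda = v, lm
        if best_var is not None:
            p = _partial_f_p(lmbda_cur, best_lmbda, n, 2, len(selected))
            if p < p_enter:
                selected.append(best_var)
                changed = True
        # removal step
        if len(selected) > 1:
            lmbda_full = wilks_lambda(table[selected].to_numpy(), y)
            worst_var, worst_p = None, -1.0
            for v in selected:
                rest = [s for s in selected if s != v]
                lm_rest = wilks_lambda(table[rest].to_numpy(), y)
                p = _partial_f_p(lm_rest, lmbda_full, n, 2, len(rest))
                if p > worst_p:
                    worst_var, worst_p = v, p
            if worst_p > p_remove:
                selected.remove(worst_var)
                changed = True
        if not changed:
            break

    if not selected:
        majority = table[group_col].value_counts().idxmax()
        pred = np.full(n, majority, dtype=object)
        logger.info("no variable passed entry; falling back to majority class %r", majority)
        return _score(groups, y, pred, selected, 1.0, 1.0)
    return fit_lda(table, selected, group_col, leave_one_out=leave_one_out)


def fit_lda(
    table: pd.DataFrame,
    variables: list[str],
    group_col: str = "group",
    leave_one_out: bool = False,
) -> DiscriminantResult:
    """Linear discriminant on a fixed variable set with equal priors.

    Reports Wilks' Λ of the fitted set, its Rao-F model p-value, and
    the resubstitution (or leave-one-out) confusion matrix and
    accuracies.
    """
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly two groups, found {groups}")
    y = table[group_col].to_numpy()
    n = len(table)
    X = table[list(variables)].to_numpy(dtype=float)
    lmbda = wilks_lambda(X, y)
    p_model = _wilks_model_p(lmbda, n, len(variables))
    if leave_one_out:
        pred = np.empty(n, dtype=object)
        for i in range(n):
            keep = np.arange(n) != i
            fold = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X[keep], y[keep])
            pred[i] = fold.predict(X[[i]])[0]
    else:
        pred = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y).predict(X)
    return _score(groups, y, pred, list(variables), lmbda, p_model)


def _score(groups, y, pred, selected, lmbda, p_model) -> DiscriminantResult:
    n = len(y)
    confusion = np.zeros((2, 2), dtype=int)
    for i, gi in enumerate(groups):
        for j, gj in enumerate(groups):
            confusion[i, j] = int(((y == gi) & (pred == gj)).sum())
    acc = 100.0 * np.trace(confusion) / n
    per_group = {
        g: 100.0 * confusion[i, i] / max(confusion[i].sum(), 1) for i, g in enumerate(groups)
    }
    return DiscriminantResult(
        selected_variables=selected,
        wilks_lambda=lmbda,
        p_value=p_model,
        confusion=confusion,
        accuracy_overall=acc,
        accuracy_per_group=per_group,
        group_order=list(groups),
    )


def _wilks_model_p(lmbda: float, n: int, p: int, n_groups: int = 2) -> float:
    """Overall model significance via Rao's F approximation (2 groups)."""
    if lmbda <= 0:
        return 0.0
    df2 = n - n_groups - p + 1
    if df2 <= 0:
        return 1.0
    f = (1.0 - lmbda) / lmbda * df2 / p
    return float(sps.f.sf(f, p, df2))


# ---------------------------------------------------------------------------
# cohort simulation from printed summaries


def simulate_cohort(
    summary: dict[str, dict[str, tuple[float, float]]],
    n_per_group: dict[str, int] | int,
    seed: int,
    group_col: str = "group",
    truncate_at_zero: bool = True,
) -> pd.DataFrame:
    """Draw a synthetic cohort from per-group (mean, SD) summaries.

    ``summary`` maps group → variable → (mean, sd).  Variables are
    drawn independently from normal laws, truncated at zero for
    non-negative morphometric quantities.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for group, variables in summary.items():
        n = n_per_group[group] if isinstance(n_per_group, dict) else int(n_per_group)
        if n < 0:
            raise ValueError("group size must be non-negative")
        cols: dict[str, np.ndarray] = {}
        for var, (mean, sd) in variables.items():
            if sd < 0:
                raise ValueError(f"negative sd for {var}")
            if sd == 0:
                cols[var] = np.full(n, mean)
            elif truncate_at_zero:
                a = (0.0 - mean) / sd
                cols[var] = sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                                              size=n, random_state=rng)
            else:
                cols[var] = rng.normal(mean, sd, size=n)
        frame = pd.DataFrame(cols)
        frame.insert(0, group_col, group)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
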