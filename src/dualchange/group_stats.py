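"""Group-level inference: multivariate pre/post tests, effect sizes,
baseline-stratified comparisons and robustness checks.

The three multivariate designs used are a one-sample Hotelling T^2 on
difference scores (repeated-measures time effect), a two-sample
Hotelling T^2 on baseline scores (group effect) and the same two-sample
test applied to difference scores (time x group interaction).  For these
single-df multivariate effects partial eta squared equals 1 - Wilks
lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DegenerateStatisticsError, InputError

__all__ = [
    "ManovaResult",
    "PairedTestResult",
    "StratifiedTestResult",
    "CorrelationResult",
    "paired_rm_anova",
    "one_sample_manova",
    "two_group_manova",
    "partial_eta_from_f",
    "eta_from_lambda",
    "baseline_stratified_change_test",
    "mann_whitney_check",
    "outcome_correlations",
    "flag_univariate_outliers",
    "rank_inverse_normal",
]


@dataclass(frozen=True)
class ManovaResult:
    """Wilks lambda, Hotelling T^2, exact F with df, p and partial eta^2."""

    wilks_lambda: float
    hotelling_t2: float
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    partial_eta_sq: float


@dataclass(frozen=True)
class PairedTestResult:
    """Univariate pre/post test: F(1, n-1) = (paired t)^2."""

    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    partial_eta_sq: float
    t_stat: float
    mean_diff: float


@dataclass(frozen=True)
class StratifiedTestResult:
    """Two-sample comparison of change scores between baseline strata."""

    outcome: str
    n_problematic: int
    n_healthy: int
    pre_mean_problematic: float
    pre_sd_problematic: float
    post_mean_problematic: float
    post_sd_problematic: float
    pre_mean_healthy: float
    pre_sd_healthy: float
    post_mean_healthy: float
    post_sd_healthy: float
    t_stat: float
    df: float
    p_value: float
    cohen_d: float
    mode: str  # "welch" | "pooled"


@dataclass(frozen=True)
class CorrelationResult:
    matrix: pd.DataFrame
    undefined: tuple[str, ...]  # constant outcomes with undefined entries


def partial_eta_from_f(f_stat: float, df1: float, df2: float) -> float:
    """Partial eta squared from an F statistic: F*df1 / (F*df1 + df2)."""
    if f_stat < 0:
        raise InputError(f"F must be >= 0, got {f_stat}")
    if df1 < 1 or df2 < 1:
        raise InputError("degrees of freedom must be >= 1")
    return float(f_stat * df1 / (f_stat * df1 + df2))


def eta_from_lambda(wilks_lambda: float) -> float:
    """Partial eta squared for a single-df multivariate effect: 1 - lambda."""
    if not 0 < wilks_lambda <= 1:
        raise InputError(f"Wilks lambda must be in (0, 1], got {wilks_lambda}")
    return float(1.0 - wilks_lambda)


def paired_rm_anova(pre: Sequence[float], post: Sequence[float]) -> PairedTestResult:
    """Repeated-measures ANOVA with one within factor at two levels.

    Equivalent to the squared paired t test: F = t^2 with df (1, n-1)
    and partial eta^2 = F / (F + n - 1).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise InputError("pre and post must be equal-length 1-d vectors")
    n = len(pre)
    if n < 2:
        raise InputError("paired test needs n >= 2")
    if np.isnan(pre).any() or np.isnan(post).any():
        raise InputError("complete cases required")
    diffs = post - pre
    sd = np.std(diffs, ddof=1)
    if sd == 0:
        if np.all(diffs == 0):
            return PairedTestResult(0.0, 1, n - 1, 1.0, 0.0, 0.0, 0.0)
        raise DegenerateStatisticsError("zero variance of difference scores")
    t = float(np.mean(diffs) / (sd / np.sqrt(n)))
    f = t * t
    p = float(stats.f.sf(f, 1, n - 1))
    return PairedTestResult(
        f_stat=f,
        df_num=1,
        df_den=n - 1,
        p_value=p,
        partial_eta_sq=partial_eta_from_f(f, 1, n - 1),
        t_stat=t,
        mean_diff=float(np.mean(diffs)),
    )


def _solve_spd(S: np.ndarray, v: np.ndarray, context: str) -> np.ndarray:
    from scipy.linalg import LinAlgError, cho_factor, cho_solve

    try:
        factor = cho_factor(S)
    except LinAlgError as exc:
        raise DataError(
            f"{context}: covariance matrix is singular; remove a redundant outcome"
        ) from exc
    if np.linalg.cond(S) > 1e12:
        raise DataError(
            f"{context}: covariance matrix is near-singular; remove a redundant outcome"
        )
    return cho_solve(factor, v)


def one_sample_manova(diff_matrix) -> ManovaResult:
    """One-sample Hotelling T^2 on a participants x outcomes difference matrix.

    T^2 = n * dbar' S^-1 dbar; Wilks lambda = 1 / (1 + T^2/(n-1));
    exact F = T^2 (n - p) / (p (n - 1)) with df (p, n - p).
    """
    d = np.atleast_2d(np.asarray(diff_matrix, dtype=float))
    n, p = d.shape
    if p < 1 or n <= p:
        raise DataError(f"one_sample_manova needs n > p >= 1, got n={n}, p={p}")
    if np.isnan(d).any():
        raise InputError("complete cases required")
    dbar = d.mean(axis=0)
    if np.allclose(d, 0):
        return ManovaResult(1.0, 0.0, 0.0, p, n - p, 1.0, 0.0)
    S = np.cov(d, rowvar=False, ddof=1).reshape(p, p)
    t2 = float(n * dbar @ _solve_spd(S, dbar, "one_sample_manova"))
    lam = 1.0 / (1.0 + t2 / (n - 1))
    f = t2 * (n - p) / (p * (n - 1))
    p_value = float(stats.f.sf(f, p, n - p))
    return ManovaResult(
        wilks_lambda=float(lam),
        hotelling_t2=t2,
        f_stat=float(f),
        df_num=p,
        df_den=n - p,
        p_value=p_value,
        partial_eta_sq=float(1.0 - lam),
    )


def two_group_manova(value_matrix, groups) -> ManovaResult:
    """Two-sample Hotelling T^2 on a participants x outcomes matrix.

    Wilks lambda = 1 / (1 + T^2/(n1+n2-2)); exact
    F = T^2 (n1+n2-p-1) / (p (n1+n2-2)) with df (p, n1+n2-p-1).
    """
    x = np.atleast_2d(np.asarray(value_matrix, dtype=float))
    g = np.asarray(groups)
    if len(g) != x.shape[0]:
        raise InputError("groups must have one label per row")
    labels = pd.unique(g)
    if len(labels) != 2:
        raise DataError(f"two_group_manova needs exactly 2 groups, got {len(labels)}")
    x1, x2 = x[g == labels[0]], x[g == labels[1]]
    n1, n2 = len(x1), len(x2)
    p = x.shape[1]
    if n1 < 2 or n2 < 2:
        raise DataError("each group needs at least 2 members")
    if n1 + n2 - 2 <= p:
        raise DataError(f"needs n1+n2-2 > p, got n1={n1}, n2={n2}, p={p}")
    if np.isnan(x).any():
        raise InputError("complete cases required")
    mean_gap = x1.mean(axis=0) - x2.mean(axis=0)
    S1 = np.cov(x1, rowvar=False, ddof=1).reshape(p, p)
    S2 = np.cov(x2, rowvar=False, ddof=1).reshape(p, p)
    Sp = ((n1 - 1) * S1 + (n2 - 1) * S2) / (n1 + n2 - 2)
    t2 = float(
        (n1 * n2 / (n1 + n2)) * mean_gap @ _solve_spd(Sp, mean_gap, "two_group_manova")
    )
    m = n1 + n2 - 2
    lam = 1.0 / (1.0 + t2 / m)
    df_den = n1 + n2 - p - 1
    f = t2 * df_den / (p * m)
    p_value = float(stats.f.sf(f, p, df_den))
    return ManovaResult(
        wilks_lambda=float(lam),
        hotelling_t2=t2,
        f_stat=float(f),
        df_num=p,
        df_den=df_den,
        p_value=p_value,
        partial_eta_sq=float(1.0 - lam),
    )


def baseline_stratified_change_test(
    outcome: str,
    pre: Sequence[float],
    post: Sequence[float],
    problematic: Sequence[bool],
    mode: str = "welch",
) -> StratifiedTestResult:
    """Compare change scores between problematic vs healthy baseline strata.

    Two-sample t on (post - pre), Welch-corrected by default; Cohen's d
    is the difference in mean change divided by the pooled SD of the
    change scores.
    """
    if mode not in ("welch", "pooled"):
        raise InputError(f"mode must be 'welch' or 'pooled', got {mode!r}")
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    flags = np.asarray(problematic, dtype=bool)
    if not (len(pre) == len(post) == len(flags)):
        raise InputError("pre, post and flags must align")
    change = post - pre
    c1, c2 = change[flags], change[~flags]
    if len(c1) < 2 or len(c2) < 2:
        raise DataError(f"{outcome}: a baseline stratum has fewer than 2 members")
    res = stats.ttest_ind(c1, c2, equal_var=(mode == "pooled"))
    n1, n2 = len(c1), len(c2)
    pooled_var = (
        (n1 - 1) * np.var(c1, ddof=1) + (n2 - 1) * np.var(c2, ddof=1)
    ) / (n1 + n2 - 2)
    d = float((c1.mean() - c2.mean()) / np.sqrt(pooled_var)) if pooled_var > 0 else 0.0
    return StratifiedTestResult(
        outcome=outcome,
        n_problematic=n1,
        n_healthy=n2,
        pre_mean_problematic=float(pre[flags].mean()),
        pre_sd_problematic=float(np.std(pre[flags], ddof=1)),
        post_mean_problematic=float(post[flags].mean()),
        post_sd_problematic=float(np.std(post[flags], ddof=1)),
        pre_mean_healthy=float(pre[~flags].mean()),
        pre_sd_healthy=float(np.std(pre[~flags], ddof=1)),
        post_mean_healthy=float(post[~flags].mean()),
        post_sd_healthy=float(np.std(post[~flags], ddof=1)),
        t_stat=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        cohen_d=d,
        mode=mode,
    )


def mann_whitney_check(values: Sequence[float], groups) -> tuple[float, float]:
    """Rank-sum robustness check; returns (U, two-sided p).

    Reported alongside the t test, never replacing it.
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = pd.unique(g)
    if len(labels) != 2:
        raise DataError("mann_whitney_check needs exactly 2 groups")
    a, b = x[g == labels[0]], x[g == labels[1]]
    if len(a) == 0 or len(b) == 0:
        raise DataError("both groups must be nonempty")
    if np.all(x == x[0]):
        raise DegenerateStatisticsError("all values tied; rank test degenerate")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def outcome_correlations(panel: pd.DataFrame, outcomes: Sequence[str]) -> CorrelationResult:
    """Outcome x outcome Pearson correlation matrix at one timepoint.

    Constant outcomes yield undefined (NaN) off-diagonal entries and are
    listed in ``undefined``; the diagonal is always 1.
    """
    if len(panel) < 3:
        raise InputError("outcome_correlations needs >= 3 participants")
    sub = panel[list(outcomes)].astype(float)
    if sub.isna().any().any():
        raise InputError("complete cases required")
    undefined = tuple(c for c in outcomes if sub[c].nunique() == 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # corr of constant column warns
        mat = sub.corr()
    np.fill_diagonal(mat.values, 1.0)
    return CorrelationResult(matrix=mat, undefined=undefined)


def flag_univariate_outliers(
    scores: pd.DataFrame,
    threshold: float = 3.29,
) -> pd.Series:
    """Flag rows with |z| above ``threshold`` on any column.

    Flag-and-report only: exclusion is an explicit user action recorded
    in the run log.  Zero-SD columns produce no flags (with a warning).
    """
    if len(scores) < 3:
        raise InputError("outlier flagging needs n >= 3")
    flags = pd.Series(False, index=scores.index)
    for col in scores.columns:
        x = scores[col].to_numpy(dtype=float)
        sd = np.std(x, ddof=1)
        if sd == 0:
            warnings.warn(f"{col}: zero SD, no outlier flags computed")
            continue
        z = np.abs((x - x.mean()) / sd)
        flags |= pd.Series(z > threshold, index=scores.index)
    return flags


def rank_inverse_normal(x: Sequence[float]) -> np.ndarray:
    """Rank-based inverse-normal transform (Blom offsets), for the optional
    robustness re-run of nonnormal outcomes."""
    x = np.asarray(x, dtype=float)
    ranks = stats.rankdata(x)
    return stats.norm.ppf((ranks - 0.375) / (len(x) + 0.25))
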