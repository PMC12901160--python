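"""Nonparametric cohort statistics for per-patient summaries.

Group comparisons use the two-tailed Mann–Whitney U test: exact enumeration
whenever both samples are small and tie-free, otherwise the normal
approximation with tie-corrected variance and continuity correction.
Families of comparisons ("multiple Mann–Whitney") are reported both
unadjusted and with Holm–Šídák step-down adjustment. Correlations use the
tie-aware Spearman coefficient. Descriptives are median and IQR with
quartiles by linear interpolation between order statistics (type 7; note
this differs from some GUI statistics packages' quartile convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

#: Use exact enumeration when n_x * n_y is at most this and there are no ties.
DEFAULT_EXACT_BOUND = 10_000


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample or correlation test."""

    statistic: float
    p_value: float
    method: str  # "exact" or "normal_approx" (or "t_approx"/"exact_perm" for rho)
    n_x: int
    n_y: int
    adjusted_p: float | None = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    exact_bound: int = DEFAULT_EXACT_BOUND,
) -> TestResult:
    """Two-tailed Mann–Whitney U test of ``x`` versus ``y``.

    The statistic is U of ``x``: the number of pairs (i, j) with
    ``x_i > y_j`` plus half the tied pairs. The exact null distribution is
    enumerated when ``n_x * n_y <= exact_bound`` and the pooled sample has
    no ties; otherwise the normal approximation with tie-corrected variance
    and continuity correction is used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("mann_whitney: both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (x.size * y.size <= exact_bound) and not has_ties
    res = stats.mannwhitneyu(
        x, y,
        alternative="two-sided",
        method="exact" if use_exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="exact" if use_exact else "normal_approx",
        n_x=int(x.size),
        n_y=int(y.size),
    )


def adjust_pvalues(
    pvalues: Sequence[float], method: str = "holm_sidak"
) -> np.ndarray:
    """Multiple-testing adjustment across a family of comparisons.

    ``holm_sidak`` applies the step-down rule: with the m p-values sorted
    ascending, adj_(i) = max_{j <= i} (1 - (1 - p_(j))^(m - j + 1)), clipped
    to 1 — monotone non-decreasing in rank and never below the input.
    ``none`` returns the inputs unchanged.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("adjust_pvalues: p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    if method == "holm_sidak":
        with np.errstate(divide="ignore"):  # log1p(-1) at p == 1 is benign
            return multipletests(p, method="holm-sidak")[1]
    raise ValidationError(f"unknown adjustment method {method!r}")


def spearman(x: Sequence[float], y: Sequence[float], exact_n: int = 9) -> TestResult:
    """Tie-aware Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of mid-ranks. The p-value is exact (full
    permutation enumeration of the rank assignment) for n <= ``exact_n``
    when the data are tie-free, otherwise the t-distribution approximation.
    A constant input vector makes rho undefined (NaN).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValidationError("spearman: samples must have equal length")
    n = x.size
    if n < 3:
        raise ValidationError("spearman: need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return TestResult(np.nan, np.nan, "undefined", n, n)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    tie_free = np.unique(x).size == n and np.unique(y).size == n
    if tie_free and n <= exact_n:
        p = _spearman_exact_p(rx, ry, rho)
        method = "exact_perm"
    else:
        # t approximation: t = rho * sqrt((n-2)/(1-rho^2))
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
        method = "t_approx"
    return TestResult(rho, min(p, 1.0), method, n, n)


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact p by enumerating all n! pairings of the ranks."""
    n = rx.size
    perms = np.array(list(permutations(range(n))))
    permuted = ry[perms]  # all orderings of y's ranks
    rx_c = rx - rx.mean()
    den = np.sqrt((rx_c**2).sum() * ((ry - ry.mean()) ** 2).sum())
    rhos = (permuted - ry.mean()) @ rx_c / den
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def summarize_median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear-interpolation (type-7) quartiles."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValidationError("summarize_median_iqr: empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q1), float(q3)
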