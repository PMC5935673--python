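"""Shared statistical tests with exact small-sample behaviour.

The Mann-Whitney U test switches to exact permutation enumeration when the
combined sample size is at most :data:`EXACT_ENUMERATION_MAX_N`; otherwise it
uses the tie-corrected normal approximation.  Kolmogorov-Smirnov, Spearman
rank correlation and the Shapiro-Wilk normality gate delegate to vetted
scipy routines — the contracts here are the reported decisions, not the
backends.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

from .io_formats import log

EXACT_ENUMERATION_MAX_N = 12


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    alternative: str
    method: str
    n: tuple[int, ...]

    def __post_init__(self) -> None:
        # nan marks an undefined result (e.g. correlation of a constant
        # vector) and is deliberately not coerced to a number
        if not np.isnan(self.pvalue) and not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"p-value {self.pvalue} outside [0, 1]")


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: number of (a_i, b_j) pairs with a_i > b_j, ties half."""
    diff = a[:, None] - b[None, :]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def _exact_mannwhitney(a: np.ndarray, b: np.ndarray, alternative: str) -> TestResult:
    pooled = np.concatenate([a, b])
    n_a, n_b = len(a), len(b)
    u_obs = _u_statistic(a, b)
    idx = range(n_a + n_b)
    us = np.empty(comb(n_a + n_b, n_a))
    mask = np.zeros(n_a + n_b, dtype=bool)
    for i, subset in enumerate(combinations(idx, n_a)):
        mask[:] = False
        mask[list(subset)] = True
        us[i] = _u_statistic(pooled[mask], pooled[~mask])
    total = len(us)
    if alternative == "greater":
        p = np.sum(us >= u_obs) / total
    elif alternative == "less":
        p = np.sum(us <= u_obs) / total
    else:  # two-sided: symmetric-tail reflection around n_a*n_b/2
        u_ref = n_a * n_b - u_obs
        lo, hi = min(u_obs, u_ref), max(u_obs, u_ref)
        p = (np.sum(us <= lo) + np.sum(us >= hi)) / total
        if lo == hi:
            p -= np.sum(us == lo) / total
    return TestResult(u_obs, min(float(p), 1.0), alternative,
                      "mann-whitney-exact", (n_a, n_b))


def mann_whitney_u(a, b, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test; exact enumeration for combined n <= 12.

    ``alternative='greater'`` tests that values in ``a`` are stochastically
    larger than those in ``b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if len(a) + len(b) <= EXACT_ENUMERATION_MAX_N:
        return _exact_mannwhitney(a, b, alternative)
    res = sps.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return TestResult(float(res.statistic), float(res.pvalue), alternative,
                      "mann-whitney-asymptotic", (len(a), len(b)))


def ks_two_sample(a, b) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (two-sided, asymptotic p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("empty sample")
    res = sps.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return TestResult(float(res.statistic), float(res.pvalue), "two-sided",
                      "ks-two-sample", (len(a), len(b)))


def spearman_rho(x, y, alternative: str = "two-sided") -> TestResult:
    """Tie-corrected Spearman rank correlation with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        # rank correlation of a constant vector is undefined, not zero
        return TestResult(float("nan"), float("nan"), alternative,
                          "spearman-undefined", (len(x),))
    res = sps.spearmanr(x, y, alternative=alternative)
    return TestResult(float(res.statistic), float(res.pvalue), alternative,
                      "spearman", (len(x),))


def shapiro_wilk_gate(sample, alpha: float = 0.05) -> str:
    """Normality gate used to route downstream test choices.

    Returns ``"normal"`` when the Shapiro-Wilk test does not reject at
    ``alpha``, else ``"non-normal"``; the decision is logged.
    """
    sample = np.asarray(sample, dtype=float)
    if len(sample) < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    res = sps.shapiro(sample)
    decision = "normal" if res.pvalue >= alpha else "non-normal"
    log.info("shapiro-wilk gate: n=%d W=%.4f p=%.4g -> %s",
             len(sample), res.statistic, res.pvalue, decision)
    return decision
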