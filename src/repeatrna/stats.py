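"""Exact binomial enrichment tests in log space, BH adjustment, Welch's t.

The coverage-null tests applied throughout the pipeline produce p-values
far below what linear double arithmetic can carry reliably (tail masses
down to 1e-300 and beyond when base-pair totals act as trial counts), so
every probability mass and tail sum here is accumulated in log space and
only materialised on output.  The two-sided convention is minimum
likelihood: the p-value sums P(X = x) over all x whose point probability
does not exceed P(X = k) by more than a relative 1e-7.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps
from scipy.stats import binom

#: relative tolerance for the minimum-likelihood two-sided convention
_MINLIKE_RTOL = 1e-7
#: below this, linear tail values from the incomplete-beta route are
#: replaced by explicit log-space summation
_LINEAR_FLOOR = 1e-280
_LOG10 = math.log(10.0)


@dataclass(frozen=True)
class EnrichmentResult:
    """One binomial enrichment test: k successes in n trials at null p."""

    k: int
    n: int
    p: float
    alternative: str
    log10_p: float
    p_adj: float | None = None

    @property
    def expected(self) -> float:
        return self.n * self.p

    @property
    def p_value(self) -> float:
        # subnormal/zero below ~1e-323; log10_p stays exact
        return 10.0 ** self.log10_p

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n": self.n,
            "p": self.p,
            "expected": self.expected,
            "alternative": self.alternative,
            "p_value": self.p_value,
            "log10_p": self.log10_p,
            "p_adj": self.p_adj,
        }


@dataclass(frozen=True)
class StatTestResult:
    statistic: float
    df: float
    p_value: float
    test_name: str


def _log_tail(k: int, n: int, p: float, upper: bool) -> float:
    """log P(X >= k) (upper) or log P(X <= k) (lower), X ~ Binom(n, p)."""
    if upper:
        if k <= 0:
            return 0.0
        linear = binom.sf(k - 1, n, p)
    else:
        if k >= n:
            return 0.0
        linear = binom.cdf(k, n, p)
    if linear >= _LINEAR_FLOOR:
        return math.log(linear)
    # deep tail: explicit log-sum-exp over pmf terms, walking away from the
    # mode; terms decay geometrically there so the walk is short
    step = 1 if upper else -1
    stop = n if upper else 0
    total = -math.inf
    x = k
    while True:
        hi = min(x + 511, stop) if upper else x
        lo = x if upper else max(x - 511, stop)
        xs = np.arange(lo, hi + 1)
        terms = binom.logpmf(xs, n, p)
        total = np.logaddexp(total, _logsumexp(terms))
        if (upper and hi == stop) or (not upper and lo == stop):
            break
        nxt = hi + 1 if upper else lo - 1
        if binom.logpmf(nxt, n, p) < total - 45.0:
            break
        x = nxt
    return float(min(total, 0.0))


def _logsumexp(a: np.ndarray) -> float:
    m = np.max(a)
    if not np.isfinite(m):
        return float(m)
    return float(m + np.log(np.sum(np.exp(a - m))))


def _log_two_sided(k: int, n: int, p: float) -> float:
    mode = min(n, int(math.floor((n + 1) * p)))
    lp_k = binom.logpmf(k, n, p)
    thresh = lp_k + math.log1p(_MINLIKE_RTOL)
    if k == mode:
        return 0.0
    if k < mode:
        near = _log_tail(k, n, p, upper=False)
        # smallest j > mode with logpmf(j) <= thresh (pmf decreasing there)
        lo, hi = mode + 1, n + 1
        while lo < hi:
            mid = (lo + hi) // 2
            if binom.logpmf(mid, n, p) <= thresh:
                hi = mid
            else:
                lo = mid + 1
        far = _log_tail(lo, n, p, upper=True) if lo <= n else -math.inf
    else:
        near = _log_tail(k, n, p, upper=True)
        # largest j < mode with logpmf(j) <= thresh
        lo, hi = -1, mode - 1
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if binom.logpmf(mid, n, p) <= thresh:
                lo = mid
            else:
                hi = mid - 1
        far = _log_tail(lo, n, p, upper=False) if lo >= 0 else -math.inf
    return float(min(np.logaddexp(near, far), 0.0))


def log_binom_test(k: int, n: int, p: float, alternative: str = "two_sided") -> float:
    """Natural-log p-value of the exact binomial test."""
    if not (0 <= k <= n):
        raise ValueError(f"k={k} outside [0, n={n}]")
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p={p} outside [0, 1]")
    if n == 0:
        return 0.0
    if p == 0.0:
        return 0.0 if k == 0 else -math.inf
    if p == 1.0:
        return 0.0 if k == n else -math.inf
    if alternative == "greater":
        return _log_tail(k, n, p, upper=True)
    if alternative == "less":
        return _log_tail(k, n, p, upper=False)
    if alternative == "two_sided":
        return _log_two_sided(k, n, p)
    raise ValueError(f"unknown alternative {alternative!r}")


def binomial_enrichment(
    k: int, n: int, p: float, alternative: str = "two_sided"
) -> EnrichmentResult:
    """Exact binomial test with log-space tail accumulation.

    ``alternative`` is ``greater`` (P(X >= k)), ``less`` (P(X <= k)), or
    ``two_sided`` (minimum-likelihood convention).
    """
    log_p = log_binom_test(k, n, p, alternative)
    return EnrichmentResult(
        k=int(k), n=int(n), p=float(p), alternative=alternative,
        log10_p=log_p / _LOG10,
    )


def bh_adjust(p_values) -> list:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


def adjust_enrichment(results: dict) -> dict:
    """BH-adjust a family of EnrichmentResults (adjustment in linear space)."""
    keys = list(results)
    padj = bh_adjust([results[k].p_value for k in keys])
    return {k: replace(results[k], p_adj=padj[i]) for i, k in enumerate(keys)}


def welch_t(x, y) -> StatTestResult:
    """Welch's unequal-variance two-sample t test (two-sided).

    Requires at least two observations per sample and nonzero variance in
    at least one of them.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        raise ValueError("both samples are constant")
    res = sps.ttest_ind(x, y, equal_var=False)
    return StatTestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        test_name="welch_t",
    )
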