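"""Self-contained statistical primitives used throughout the screen.

The screen's per-gene machinery is deliberately small and explicit: Spearman
rank correlation (midranks, t-approximation p), Mann-Whitney U (midrank tie
correction, exact enumeration for small samples), Student/Welch two-sample t,
a Shapiro-Wilk normality gate choosing between them, the Kaplan-Meier
product-limit estimator and the two-group log-rank test. scipy supplies only
distribution functions, midranks and the Shapiro-Wilk statistic; every test
statistic here is computed from first principles so it can be cross-checked
against independent reference implementations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
from scipy import stats as _sps

__all__ = [
    "TestResult",
    "CorrelationResult",
    "SurvivalCurve",
    "UndefinedCorrelationError",
    "spearman",
    "mann_whitney",
    "two_sample_t",
    "normality_gate",
    "gated_test",
    "km_curve",
    "restricted_mean",
    "log_rank",
    "T_TEST",
    "MANN_WHITNEY",
]

T_TEST = "T_TEST"
MANN_WHITNEY = "MANN_WHITNEY"


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is undefined (constant ranks)."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    n1: int
    n2: int


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate evaluated at the distinct observed times."""

    event_times: np.ndarray  # distinct observed times, increasing
    survival: np.ndarray  # S(t) just after each time, non-increasing
    at_risk: np.ndarray  # number at risk just before each time
    n_events: np.ndarray  # events at each time


def _as1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


# ---------------------------------------------------------------------------
# Spearman


def spearman(x, y, method: str = "t") -> CorrelationResult:
    """Spearman rank correlation with midranks.

    rho is the Pearson correlation of the midrank-transformed inputs. The
    two-sided p-value comes from the t approximation
    ``t = rho * sqrt((n - 2) / (1 - rho^2))`` on n-2 df (``method="t"``), or
    from full permutation enumeration (``method="exact"``, n <= 8). |rho| = 1
    yields p = 0.
    """
    xa, ya = _as1d(x, "x"), _as1d(y, "y")
    if xa.size != ya.size:
        raise ValueError(f"length mismatch: {xa.size} vs {ya.size}")
    n = xa.size
    if n < 3:
        raise ValueError("spearman needs at least 3 paired observations")
    rx = _sps.rankdata(xa)
    ry = _sps.rankdata(ya)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedCorrelationError("constant ranks: correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if method == "exact":
        if n > 8:
            raise ValueError("exact spearman limited to n <= 8")
        target = abs(rho) - 1e-12
        count = 0
        total = 0
        for perm in permutations(ry):
            r = float(np.corrcoef(rx, np.asarray(perm))[0, 1])
            count += abs(r) >= target
            total += 1
        return CorrelationResult(rho, count / total, n)
    if abs(rho) >= 1.0 - 1e-15:
        return CorrelationResult(round(rho), 0.0, n)
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * float(_sps.t.sf(abs(t), n - 2))
    return CorrelationResult(rho, min(p, 1.0), n)


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _tie_term(pooled_ranks: np.ndarray) -> float:
    _, counts = np.unique(pooled_ranks, return_counts=True)
    return float(np.sum(counts**3 - counts))


def mann_whitney(a, b, exact: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    Reports U of the first sample. For ``n1 + n2 <= 10`` (``exact="auto"`` or
    ``"always"``) the p-value is computed by enumerating all C(n1+n2, n1)
    group labelings of the pooled midranks: p = 2 * min(P(U <= u), P(U >= u)),
    capped at 1. Otherwise a normal approximation with tie-corrected variance
    is used.
    """
    aa, bb = _as1d(a, "a"), _as1d(b, "b")
    n1, n2 = aa.size, bb.size
    if n1 == 0 or n2 == 0:
        raise ValueError("mann_whitney requires non-empty groups")
    pooled = np.concatenate([aa, bb])
    ranks = _sps.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    use_exact = exact == "always" or (exact == "auto" and n1 + n2 <= 10)
    if use_exact:
        n = n1 + n2
        lows = highs = total = 0
        for idx in combinations(range(n), n1):
            u = float(ranks[list(idx)].sum()) - n1 * (n1 + 1) / 2.0
            lows += u <= u1 + 1e-9
            highs += u >= u1 - 1e-9
            total += 1
        p = min(1.0, 2.0 * min(lows, highs) / total)
        return TestResult(u1, p, "mann_whitney_exact", n1, n2)
    mu = n1 * n2 / 2.0
    nn = n1 + n2
    var = n1 * n2 / 12.0 * ((nn + 1) - _tie_term(ranks) / (nn * (nn - 1)))
    if var <= 0:  # all observations tied
        return TestResult(u1, 1.0, "mann_whitney", n1, n2)
    z = (u1 - mu) / math.sqrt(var)
    p = 2.0 * float(_sps.norm.sf(abs(z)))
    return TestResult(u1, min(p, 1.0), "mann_whitney", n1, n2)


# ---------------------------------------------------------------------------
# two-sample t


def two_sample_t(a, b, equal_var: bool = False) -> TestResult:
    """Student (pooled) or Welch two-sample t test, two-sided.

    The statistic's sign follows ``mean(a) - mean(b)``.
    """
    aa, bb = _as1d(a, "a"), _as1d(b, "b")
    n1, n2 = aa.size, bb.size
    if n1 < 2 or n2 < 2:
        raise ValueError("two_sample_t requires n >= 2 per group")
    v1, v2 = float(aa.var(ddof=1)), float(bb.var(ddof=1))
    diff = float(aa.mean() - bb.mean())
    if v1 == 0.0 and v2 == 0.0:
        raise ValueError("zero variance in both groups: t test undefined")
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
        name = "student_t"
    else:
        se = math.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
        name = "welch_t"
    t = diff / se
    p = 2.0 * float(_sps.t.sf(abs(t), df))
    return TestResult(t, min(p, 1.0), name, n1, n2)


# ---------------------------------------------------------------------------
# normality gate


def normality_gate(a, b, alpha_norm: float = 0.05) -> str:
    """Choose T_TEST vs MANN_WHITNEY from per-group Shapiro-Wilk.

    Returns ``T_TEST`` iff both groups have n >= 3, non-constant values and
    Shapiro-Wilk p >= ``alpha_norm``; otherwise ``MANN_WHITNEY``.
    """
    aa, bb = _as1d(a, "a"), _as1d(b, "b")
    for g in (aa, bb):
        if g.size < 3 or np.ptp(g) == 0:
            return MANN_WHITNEY
        if float(_sps.shapiro(g).pvalue) < alpha_norm:
            return MANN_WHITNEY
    return T_TEST


def gated_test(a, b, alpha_norm: float = 0.05, equal_var: bool = False):
    """Run the normality-gated two-group test.

    Returns ``(TestResult, choice)`` where choice is T_TEST or MANN_WHITNEY.
    """
    choice = normality_gate(a, b, alpha_norm)
    if choice == T_TEST:
        return two_sample_t(a, b, equal_var=equal_var), T_TEST
    return mann_whitney(a, b), MANN_WHITNEY


# ---------------------------------------------------------------------------
# survival


def km_curve(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    At tied times, events are ordered before censorings (both count as at
    risk at that time). Censored-only times appear in the grid and reduce the
    at-risk count without a survival step.
    """
    t = _as1d(times, "times")
    e = np.asarray(events, dtype=int).ravel()
    if t.size == 0:
        raise ValueError("km_curve requires at least one observation")
    if t.size != e.size:
        raise ValueError("times and events must have equal length")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    if not set(np.unique(e)) <= {0, 1}:
        raise ValueError("events must be 0/1")
    uniq = np.unique(t)
    n = t.size
    surv = np.empty(uniq.size)
    at_risk = np.empty(uniq.size, dtype=int)
    n_events = np.empty(uniq.size, dtype=int)
    s = 1.0
    for i, ti in enumerate(uniq):
        ni = int(np.sum(t >= ti))
        di = int(np.sum((t == ti) & (e == 1)))
        at_risk[i] = ni
        n_events[i] = di
        if di:
            s *= 1.0 - di / ni
        surv[i] = s
    return SurvivalCurve(uniq, surv, at_risk, n_events)


def restricted_mean(curve: SurvivalCurve, tau: float) -> float:
    """Restricted mean survival time: integral of S(t) over [0, tau].

    S is the usual right-continuous step function (S = 1 before the first
    observed time, constant after the last).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    area = 0.0
    prev_t, prev_s = 0.0, 1.0
    for t, s in zip(curve.event_times, curve.survival):
        if t >= tau:
            break
        area += prev_s * (t - prev_t)
        prev_t, prev_s = float(t), float(s)
    area += prev_s * (tau - prev_t)
    return area


def log_rank(times1, events1, times2, events2) -> TestResult:
    """Two-group log-rank test (1 df chi-square, hypergeometric variance).

    With no events in the pooled data (or zero variance) the statistic is 0
    and p = 1.
    """
    t1, t2 = _as1d(times1, "times1"), _as1d(times2, "times2")
    e1 = np.asarray(events1, dtype=int).ravel()
    e2 = np.asarray(events2, dtype=int).ravel()
    if t1.size == 0 or t2.size == 0:
        raise ValueError("log_rank requires non-empty groups")
    t = np.concatenate([t1, t2])
    e = np.concatenate([e1, e2])
    grp = np.concatenate([np.zeros(t1.size, dtype=int), np.ones(t2.size, dtype=int)])
    event_times = np.unique(t[e == 1])
    o1 = e1_exp = var = 0.0
    for ti in event_times:
        at = t >= ti
        n = int(at.sum())
        n1 = int((at & (grp == 0)).sum())
        d = int(((t == ti) & (e == 1)).sum())
        d1 = int(((t == ti) & (e == 1) & (grp == 0)).sum())
        o1 += d1
        e1_exp += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        return TestResult(0.0, 1.0, "log_rank", t1.size, t2.size)
    stat = (o1 - e1_exp) ** 2 / var
    p = float(_sps.chi2.sf(stat, df=1))
    return TestResult(stat, p, "log_rank", t1.size, t2.size)
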