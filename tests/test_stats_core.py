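"""Unit and property tests for the statistical primitives, each cross-checked
against an independent route (explicit enumeration, hand formulas, scipy or
lifelines reference implementations)."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from bonescreen.stats_core import (
    MANN_WHITNEY,
    T_TEST,
    UndefinedCorrelationError,
    gated_test,
    km_curve,
    log_rank,
    mann_whitney,
    normality_gate,
    restricted_mean,
    spearman,
    two_sample_t,
)

# ---------------------------------------------------------------------------
# independent oracles


def midranks(values):
    """Explicit midrank construction (average rank over tied positions)."""
    values = list(values)
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson_by_sums(x, y):
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x) - sx * sx / n
    syy = sum(v * v for v in y) - sy * sy / n
    sxy = sum(a * b for a, b in zip(x, y)) - sx * sy / n
    return sxy / math.sqrt(sxx * syy)


def mw_enumeration_p(a, b):
    """Exact two-sided Mann-Whitney p over all group labelings."""
    pooled = list(a) + list(b)
    ranks = midranks(pooled)
    n1 = len(a)
    u_obs = sum(ranks[: n1]) - n1 * (n1 + 1) / 2
    lows = highs = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2
        lows += u <= u_obs + 1e-9
        highs += u >= u_obs - 1e-9
        total += 1
    return min(1.0, 2 * min(lows, highs) / total)


# ---------------------------------------------------------------------------
# Spearman


def test_spearman_perfect_monotone():
    assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).rho == pytest.approx(1.0)
    assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).p_value == 0.0
    assert spearman([1, 2, 3, 4], [4, 3, 2, 1]).rho == pytest.approx(-1.0)


def test_spearman_hand_midrank_example():
    # ranks of y = (1, 2, 3.5, 5, 3.5); Pearson on ranks = 8 / sqrt(95)
    res = spearman([1, 2, 3, 4, 5], [5, 6, 7, 8, 7])
    assert res.rho == pytest.approx(8 / math.sqrt(95), abs=1e-12)


def test_spearman_equals_bruteforce_all_permutations():
    """rho matches Pearson on explicitly constructed midranks for every
    permutation of a tied multiset (n = 6, 720 orderings)."""
    x = [3.0, 1.0, 4.0, 1.0, 5.0, 9.0]
    rx = midranks(x)
    for perm in itertools.permutations([1.0, 2.0, 2.0, 3.0, 3.0, 3.0]):
        expected = pearson_by_sums(rx, midranks(perm))
        got = spearman(x, perm).rho
        assert abs(got - expected) < 1e-12


def test_spearman_matches_scipy():
    rng = np.random.default_rng(7)
    x = rng.normal(size=40)
    y = rng.normal(size=40) + 0.5 * x
    res = spearman(x, y)
    ref = sps.spearmanr(x, y)
    assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


def test_spearman_errors():
    with pytest.raises(ValueError, match="length"):
        spearman([1, 2, 3], [1, 2])
    with pytest.raises(ValueError, match="at least 3"):
        spearman([1, 2], [1, 2])
    with pytest.raises(UndefinedCorrelationError):
        spearman([1, 1, 1], [1, 2, 3])


def test_spearman_exact_mode_small_n():
    res_t = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
    res_e = spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4], method="exact")
    assert res_e.rho == pytest.approx(res_t.rho)
    # permutation p is a multiple of 1/120 and within the same ballpark
    assert res_e.p_value * 120 == pytest.approx(round(res_e.p_value * 120))


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.lists(st.integers(-50, 50), min_size=4, max_size=25, unique=True))
def test_spearman_invariant_under_monotone_transforms(xs):
    xs = [float(v) for v in xs]
    rng = np.random.default_rng(42)
    ys = rng.permutation(len(xs)).astype(float)
    base = spearman(xs, ys).rho
    for fx in (np.exp(np.asarray(xs) / 50.0), np.asarray(xs) ** 3, 3.0 * np.asarray(xs) + 7):
        assert spearman(fx, ys).rho == pytest.approx(base, abs=1e-12)


# ---------------------------------------------------------------------------
# Mann-Whitney


def test_mann_whitney_separated_groups_exact():
    res = mann_whitney([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(0.1)  # 2/20 labelings


def test_mann_whitney_identical_groups():
    assert mann_whitney([1, 2, 2, 3], [1, 2, 2, 3]).p_value == pytest.approx(1.0)


@pytest.mark.parametrize(
    "a,b",
    [
        ([1, 2, 3], [2.5, 4, 6, 7]),
        ([1.0, 1.0, 2.0], [1.0, 3.0, 3.0, 5.0]),  # ties across groups
        ([10, 11], [1, 2, 3, 4, 5]),
    ],
)
def test_mann_whitney_exact_equals_enumeration(a, b):
    assert mann_whitney(a, b).p_value == pytest.approx(mw_enumeration_p(a, b), abs=1e-12)


def test_mann_whitney_symmetry():
    rng = np.random.default_rng(3)
    a, b = rng.normal(size=15), rng.normal(size=20) + 0.7
    assert mann_whitney(a, b).p_value == pytest.approx(mann_whitney(b, a).p_value, abs=1e-12)


def test_mann_whitney_normal_approx_matches_scipy():
    rng = np.random.default_rng(5)
    a = np.round(rng.normal(size=25), 1)  # rounding induces ties
    b = np.round(rng.normal(size=30) + 0.4, 1)
    res = mann_whitney(a, b)
    ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=False)
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)


def test_mann_whitney_empty_group():
    with pytest.raises(ValueError):
        mann_whitney([], [1, 2])


# ---------------------------------------------------------------------------
# t test


def test_t_identical_groups():
    res = two_sample_t([1, 2, 3], [1, 2, 3])
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_t_separated_groups():
    a = np.zeros(4) + 1e-9 * np.arange(4)
    b = np.ones(4) + 1e-9 * np.arange(4)
    assert two_sample_t(a, b).p_value < 1e-6


@pytest.mark.parametrize("equal_var", [True, False])
def test_t_matches_scipy(equal_var):
    rng = np.random.default_rng(11)
    a = rng.normal(0, 1, size=18)
    b = rng.normal(0.5, 2, size=25)
    res = two_sample_t(a, b, equal_var=equal_var)
    ref = sps.ttest_ind(a, b, equal_var=equal_var)
    assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-8)


def test_t_errors():
    with pytest.raises(ValueError, match="n >= 2"):
        two_sample_t([1], [1, 2])
    with pytest.raises(ValueError, match="zero variance"):
        two_sample_t([2, 2, 2], [3, 3, 3])


# ---------------------------------------------------------------------------
# normality gate


def test_gate_small_group_forces_mann_whitney(rng):
    assert normality_gate([1.0, 2.0], rng.normal(size=20)) == MANN_WHITNEY


def test_gate_exponential_data_forces_mann_whitney(rng):
    a = rng.normal(size=200)
    b = rng.exponential(1.0, size=200)
    assert normality_gate(a, b) == MANN_WHITNEY


def test_gate_normal_data_mostly_t():
    hits = 0
    for seed in range(100):
        r = np.random.default_rng(seed)
        if normality_gate(r.normal(size=50), r.normal(size=50)) == T_TEST:
            hits += 1
    assert hits >= 90  # each group fails Shapiro-Wilk ~5% of the time


def test_gated_test_returns_choice(rng):
    res, used = gated_test(rng.normal(size=30), rng.normal(size=30))
    assert used in (T_TEST, MANN_WHITNEY)
    assert 0 <= res.p_value <= 1


# ---------------------------------------------------------------------------
# Kaplan-Meier


def test_km_no_censoring_is_empirical_survivor():
    c = km_curve([1, 2, 3], [1, 1, 1])
    np.testing.assert_allclose(c.survival, [2 / 3, 1 / 3, 0.0])
    # 1 - ECDF at each event time, for arbitrary uncensored data
    rng = np.random.default_rng(9)
    t = rng.exponential(10, size=50)
    c = km_curve(t, np.ones(50, dtype=int))
    for ti, si in zip(c.event_times, c.survival):
        assert si == pytest.approx(np.mean(t > ti))


def test_km_all_censored_flat():
    c = km_curve([5, 1, 3], [0, 0, 0])
    np.testing.assert_allclose(c.survival, [1.0, 1.0, 1.0])
    np.testing.assert_array_equal(c.at_risk, [3, 2, 1])


def test_km_worked_censored_example():
    # censor at t=2 ranked after the event at t=2: at-risk there is 3
    c = km_curve([1, 2, 2, 3], [1, 0, 1, 1])
    np.testing.assert_allclose(c.survival, [3 / 4, 1 / 2, 0.0], atol=1e-15)
    np.testing.assert_array_equal(c.at_risk, [4, 3, 1])


def test_km_matches_lifelines(rng):
    from lifelines import KaplanMeierFitter

    t = np.round(rng.exponential(10, size=80), 1) + 0.1
    e = rng.integers(0, 2, size=80)
    c = km_curve(t, e)
    kmf = KaplanMeierFitter().fit(t, e)
    for ti, si in zip(c.event_times, c.survival):
        assert si == pytest.approx(kmf.predict(ti), abs=1e-10)


def test_km_monotone_and_bounded(rng):
    t = rng.exponential(5, size=60)
    e = rng.integers(0, 2, size=60)
    c = km_curve(t, e)
    assert c.survival[0] <= 1
    assert np.all(np.diff(c.survival) <= 1e-15)
    assert np.all(np.diff(c.at_risk) < 0)


def test_restricted_mean_exponential(rng):
    # RMST of the KM estimate approximates the integral of the true survivor
    t = rng.exponential(10, size=4000)
    c = km_curve(t, np.ones(t.size, dtype=int))
    assert restricted_mean(c, 10.0) == pytest.approx(10 * (1 - math.exp(-1)), rel=0.05)


# ---------------------------------------------------------------------------
# log-rank


def test_logrank_identical_groups():
    res = log_rank([1, 2, 3], [1, 1, 1], [1, 2, 3], [1, 1, 1])
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_logrank_hand_toy():
    # O1 = 3, E1 = 0.5 + 0.4 + 0.25, V = 0.25 + 0.24 + 0.1875
    res = log_rank([1, 2, 3], [1, 1, 1], [4, 5, 6], [1, 1, 1])
    assert res.statistic == pytest.approx((3 - 1.15) ** 2 / 0.6775, abs=1e-12)
    assert res.statistic == pytest.approx(5.05, abs=0.01)
    assert res.p_value == pytest.approx(0.025, abs=0.001)


def test_logrank_symmetric_in_labels(rng):
    t1, t2 = rng.exponential(5, size=30), rng.exponential(8, size=25)
    e1, e2 = rng.integers(0, 2, size=30), rng.integers(0, 2, size=25)
    a = log_rank(t1, e1, t2, e2)
    b = log_rank(t2, e2, t1, e1)
    assert a.statistic == pytest.approx(b.statistic, abs=1e-10)


def test_logrank_no_events():
    res = log_rank([1, 2], [0, 0], [3, 4], [0, 0])
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_logrank_matches_lifelines(rng):
    from lifelines.statistics import logrank_test

    t1 = rng.exponential(5, size=40)
    t2 = rng.exponential(9, size=35)
    e1 = rng.integers(0, 2, size=40)
    e2 = rng.integers(0, 2, size=35)
    res = log_rank(t1, e1, t2, e2)
    ref = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
    assert res.statistic == pytest.approx(ref.test_statistic, abs=1e-8)
    assert res.p_value == pytest.approx(ref.p_value, abs=1e-8)


def test_logrank_null_p_values_uniform():
    """Under exponential null arms the p-value is ~U(0,1) (KS check)."""
    rng = np.random.default_rng(2022)
    ps = []
    for _ in range(400):
        t1 = rng.exponential(10, size=50)
        t2 = rng.exponential(10, size=50)
        c = rng.uniform(0, 30, size=100)
        t = np.concatenate([t1, t2])
        e = (t <= c).astype(int)
        obs = np.minimum(t, c)
        ps.append(log_rank(obs[:50], e[:50], obs[50:], e[50:]).p_value)
    d = sps.kstest(ps, "uniform").statistic
    assert d < 0.07  # 400 replicates; spec-scale run (2000) is in acceptance
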