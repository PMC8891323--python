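"""Survival/statistics primitives vs brute-force and hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.optimize import minimize_scalar

from irlncpair.stats import (bh_fdr, breslow_loglik, chisq_test, cox1, cox_fit,
                             km_curve, km_survival_at, kruskal_test,
                             logrank_test, pearson_test, ranksum_test,
                             spearman_test)


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

def test_km_all_events_product_limit():
    km = km_curve([1, 2, 3], [1, 1, 1])
    assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
    assert km.evaluate(0.5) == 1.0


def test_km_all_censored_flat():
    km = km_curve([1, 2, 3], [0, 0, 0])
    assert np.allclose(km.survival, 1.0)


def test_km_mixed_hand_computed():
    # hand product-limit: S = 5/6, 2/3, 4/9, 4/9, 0 at t = 1,2,3,4,5
    times = [1, 2, 2, 3, 4, 5]
    events = [1, 0, 1, 1, 0, 1]
    km = km_curve(times, events)
    assert km.evaluate(1) == pytest.approx(5 / 6)
    assert km.evaluate(2) == pytest.approx(2 / 3)
    assert km.evaluate(3) == pytest.approx(4 / 9)
    assert km.evaluate(4.9) == pytest.approx(4 / 9)
    assert km.evaluate(5) == pytest.approx(0.0)
    for t in (0.5, 1, 2, 3, 4, 5, 6):
        assert km_survival_at(times, events, t) == pytest.approx(km.evaluate(t))


def test_km_rejects_empty_and_nonpositive():
    with pytest.raises(ValueError):
        km_curve([], [])
    with pytest.raises(ValueError):
        km_curve([0, 1], [1, 1])


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

def _logrank_oracle_2group(g, t, e):
    """Textbook O−E chi-square for two groups."""
    g, t, e = np.asarray(g), np.asarray(t, float), np.asarray(e, int)
    O = E = V = 0.0
    for tt in np.unique(t[e == 1]):
        at_risk = t >= tt
        n, n1 = at_risk.sum(), (at_risk & (g == 1)).sum()
        d = ((t == tt) & (e == 1)).sum()
        d1 = ((t == tt) & (e == 1) & (g == 1)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


def test_logrank_identical_groups_zero():
    t = [1, 2, 3, 4, 1, 2, 3, 4]
    e = [1, 1, 0, 1, 1, 1, 0, 1]
    g = [0, 0, 0, 0, 1, 1, 1, 1]
    stat, df, p = logrank_test(g, t, e)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert df == 1 and p == pytest.approx(1.0)


def test_logrank_matches_hand_oe_table(rng):
    t = rng.exponential(10, 40).round(3) + 0.01
    e = rng.integers(0, 2, 40)
    e[:4] = 1
    g = np.repeat([0, 1], 20)
    stat, df, p = logrank_test(g, t, e)
    assert stat == pytest.approx(_logrank_oracle_2group(g, t, e), rel=1e-9)


def test_logrank_three_groups_df_and_signal():
    rng = np.random.default_rng(5)
    t = np.concatenate([rng.exponential(s, 30) for s in (2.0, 6.0, 18.0)]) + 0.01
    e = np.ones(90, int)
    g = np.repeat([0, 1, 2], 30)
    stat, df, p = logrank_test(g, t, e)
    assert df == 2
    assert p < 1e-6
    with pytest.raises(ValueError):
        logrank_test(np.zeros(90), t, e)


# ---------------------------------------------------------------------------
# Cox: grid-search oracle on tiny instances
# ---------------------------------------------------------------------------

def _efron_loglik_direct(beta, x, time, event):
    """Efron partial likelihood straight from the definition (O(n^2))."""
    ll = 0.0
    for tt in np.unique(time[event == 1]):
        D = np.where((time == tt) & (event == 1))[0]
        R = np.where(time >= tt)[0]
        d = len(D)
        wD = np.exp(beta * x[D]).sum()
        ll += beta * x[D].sum()
        for l in range(d):
            ll -= np.log(np.exp(beta * x[R]).sum() - (l / d) * wD)
    return ll


import functools


@functools.lru_cache(maxsize=1)
def _tiny_instance_cache():
    return _tiny_instances()


def _tiny_instances(n_instances=25, max_n=6, seed=7):
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n_instances:
        n = int(rng.integers(4, max_n + 1))
        t = rng.uniform(1, 10, n)
        if len(np.unique(t)) < n:       # keep tie-free
            continue
        e = rng.integers(0, 2, n)
        if e.sum() < 2:
            continue
        x = rng.normal(size=n)
        opt = minimize_scalar(lambda b: -_efron_loglik_direct(b, x, t, e),
                              bounds=(-8, 8), method="bounded",
                              options={"xatol": 1e-10})
        if abs(opt.x) > 5:              # near-separable; skip
            continue
        out.append((x, t, e, opt.x))
    return out


@pytest.mark.parametrize("idx", range(25))
def test_cox_matches_grid_search_oracle(idx):
    x, t, e, beta_star = _tiny_instance_cache()[idx]
    fit = cox_fit(pd.DataFrame({"x": x}), t, e)
    assert fit.table.loc["x", "coef"] == pytest.approx(beta_star, abs=1e-6)
    fast = cox1(x, t, e)
    assert fast.table.loc["x", "coef"] == pytest.approx(beta_star, abs=1e-6)
    # AIC consistency: AIC = 2k − 2 logPL with the directly evaluated likelihood
    assert fast.aic == pytest.approx(2 - 2 * _efron_loglik_direct(beta_star, x, t, e),
                                     abs=1e-5)


def test_cox1_agrees_with_lifelines_binary_covariate(rng):
    n = 120
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(10 / np.exp(0.7 * x)) + 0.01
    e = (rng.uniform(size=n) < 0.8).astype(int)
    ref = cox_fit(pd.DataFrame({"x": x}), t, e)
    fast = cox1(x, t, e)
    assert fast.table.loc["x", "coef"] == pytest.approx(ref.table.loc["x", "coef"], abs=1e-5)
    assert fast.table.loc["x", "se"] == pytest.approx(ref.table.loc["x", "se"], rel=1e-4)
    assert fast.aic == pytest.approx(ref.aic, abs=1e-4)


def test_cox_constant_covariate_rejected():
    with pytest.raises(ValueError):
        cox_fit(pd.DataFrame({"x": np.ones(10)}), np.arange(1, 11), np.ones(10, int))
    with pytest.raises(ValueError):
        cox1(np.ones(10), np.arange(1, 11), np.ones(10, int))


def test_cox_null_covariate_near_zero(rng):
    n = 300
    x = rng.normal(size=n)
    t = rng.exponential(5, n) + 0.01
    fit = cox1(x, t, np.ones(n, int))
    assert abs(fit.table.loc["x", "coef"]) < 0.15
    assert fit.table.loc["x", "p"] > 1e-3


def test_cox_separation_flagged():
    # earlier half all events with x=1: monotone likelihood
    t = np.arange(1.0, 11.0)
    x = (t <= 5).astype(float)
    e = np.ones(10, int)
    fit = cox1(x, t, e)
    assert not fit.converged


def test_breslow_loglik_matches_direct_no_ties(rng):
    n = 25
    X = rng.normal(size=(n, 3))
    beta = np.array([0.5, -0.2, 0.1])
    t = rng.uniform(1, 50, n)
    e = rng.integers(0, 2, n)
    e[0] = 1
    # without ties Breslow == Efron; compare against the direct evaluation
    direct = _efron_loglik_direct(1.0, X @ beta, t, e)
    assert breslow_loglik(X, beta, t, e) == pytest.approx(direct, rel=1e-9)


# ---------------------------------------------------------------------------
# BH-FDR
# ---------------------------------------------------------------------------

def _bh_oracle(p):
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


def test_bh_closed_form_and_single():
    assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    assert bh_fdr([0.3])[0] == pytest.approx(0.3)


def test_bh_matches_stepup_oracle(rng):
    p = rng.uniform(size=100)
    assert np.allclose(bh_fdr(p), _bh_oracle(p))


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_bh_bounded_and_rank_monotone(ps):
    p = np.asarray(ps)
    q = bh_fdr(p)
    assert (q <= 1 + 1e-12).all() and (q >= p - 1e-12).all()
    # step-up adjustment preserves the p-value ranking
    order = np.argsort(p, kind="mergesort")
    assert (np.diff(q[order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# Plain association tests
# ---------------------------------------------------------------------------

def test_correlations_trivial_cases():
    x = np.arange(10.0)
    r, p = pearson_test(x, 2 * x)
    assert r == pytest.approx(1.0)
    rho, p2 = spearman_test(x, -(x ** 3))
    assert rho == pytest.approx(-1.0)
    with pytest.raises(ValueError):
        pearson_test(x, np.ones(10))


def test_chisq_hand_formula_2x2():
    # (10,0;0,10): X^2 = N(ad-bc)^2 / (r1 r2 c1 c2) = 20*100^2/10^4 = 20
    stat, df, p = chisq_test([[10, 0], [0, 10]])
    assert stat == pytest.approx(20.0)
    assert df == 1 and p < 1e-4


@pytest.mark.parametrize("testfun", ["pearson", "ranksum"])
def test_null_pvalues_uniform(testfun):
    """Under the null, p-values are approximately Uniform(0,1) (KS check)."""
    rng = np.random.default_rng(2024)
    ps = []
    for _ in range(2000):
        if testfun == "pearson":
            ps.append(pearson_test(rng.normal(size=20), rng.normal(size=20))[1])
        else:
            ps.append(ranksum_test(rng.normal(size=18), rng.normal(size=18))[1])
    d = sps.ks_1samp(ps, sps.uniform.cdf).statistic
    assert d < 0.05


def test_ranksum_and_kruskal_basic(rng):
    a, b = rng.normal(0, 1, 50), rng.normal(2, 1, 50)
    _, p = ranksum_test(a, b)
    assert p < 1e-6
    _, p3 = kruskal_test([a, b, rng.normal(0, 1, 50)])
    assert p3 < 1e-4
    with pytest.raises(ValueError):
        ranksum_test(a, [])
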