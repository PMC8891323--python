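"""Cohort splitting and the pair-signature selection cascade."""

import numpy as np
import pandas as pd
import pytest
from sksurv.util import Surv

import irlncpair as ip
from irlncpair.pairs import pair_id
from irlncpair.signature import (PairedCoxSignature, baseline_expression_signature,
                                 build_signature, lasso_cox_cv, risk_scores,
                                 split_cohort, stepwise_cox, univariate_screen)
from irlncpair.stats import cox_fit

from conftest import surv_arrays


# ---------------------------------------------------------------------------
# split_cohort
# ---------------------------------------------------------------------------

def _clin(n=100, events=40, seed=0):
    rng = np.random.default_rng(seed)
    e = np.zeros(n, int)
    e[:events] = 1
    return pd.DataFrame({"sample_id": [f"S{i:03d}" for i in range(n)],
                         "os_days": rng.uniform(10, 2000, n),
                         "os_event": rng.permutation(e)})


def test_split_stratified_and_deterministic():
    clin = _clin()
    tr, te = split_cohort(clin, seed=3)
    assert sorted(tr + te) == sorted(clin["sample_id"])
    assert not set(tr) & set(te)
    ev = clin.set_index("sample_id")["os_event"]
    assert abs(ev.loc[tr].sum() - 20) <= 2
    assert abs(ev.loc[tr].mean() - ev.loc[te].mean()) <= 0.05
    tr2, te2 = split_cohort(clin, seed=3)
    assert tr == tr2 and te == te2
    assert split_cohort(clin, seed=4)[0] != tr


def test_split_odd_n_sizes_differ_by_one():
    clin = _clin(n=101, events=41)
    tr, te = split_cohort(clin, seed=0)
    assert abs(len(tr) - len(te)) == 1


def test_split_too_few_samples():
    with pytest.raises(ValueError):
        split_cohort(_clin(n=10, events=5), seed=0)


# ---------------------------------------------------------------------------
# univariate screen
# ---------------------------------------------------------------------------

def test_univariate_screen_power_and_skip(small_bundle, small_pairmatrix):
    t, e = surv_arrays(small_bundle.clinical)
    pm = small_pairmatrix.copy()
    pm.loc["CONST"] = 1   # constant pair must be skipped
    tab = univariate_screen(pm, t, e)
    assert "CONST" not in tab.index
    planted = [pair_id(a, b) for (a, b), _ in small_bundle.truth.planted_pairs]
    present = [p for p in planted if p in tab.index]
    assert len(present) == 4
    assert tab.loc[present, "selected"].all()      # power ~ 1 at beta 0.8, n 250
    # estimated sign matches planted sign
    for (a, b), beta in small_bundle.truth.planted_pairs:
        assert np.sign(tab.loc[pair_id(a, b), "coef"]) == np.sign(beta)


def test_univariate_null_type_one_rate(rng):
    n = 300
    t = rng.exponential(1000, n) + 1
    e = (rng.uniform(size=n) < 0.7).astype(int)
    pm = pd.DataFrame(rng.integers(0, 2, size=(400, n)),
                      index=[f"P{i}" for i in range(400)],
                      columns=[f"S{i}" for i in range(n)])
    tab = univariate_screen(pm, t, e)
    rate = tab["selected"].mean()
    assert 0.02 <= rate <= 0.09


# ---------------------------------------------------------------------------
# lasso
# ---------------------------------------------------------------------------

def test_lasso_limits_and_strong_pair(small_bundle, small_pairmatrix):
    t, e = surv_arrays(small_bundle.clinical)
    pm = small_pairmatrix
    planted = [pair_id(a, b) for (a, b), _ in small_bundle.truth.planted_pairs]
    strong = pm.loc[[planted[0]] + [p for p in pm.index if p not in planted][:20]]
    res = lasso_cox_cv(strong, t, e, folds=10, seed=0)
    assert planted[0] in res["survivors"]
    # huge penalty: everything shrinks to zero
    res_inf = lasso_cox_cv(strong, t, e, penalty=1e3)
    assert res_inf["survivors"] == []


def test_lasso_tiny_penalty_matches_unpenalized(small_bundle, small_pairmatrix):
    t, e = surv_arrays(small_bundle.clinical)
    planted = [pair_id(a, b) for (a, b), _ in small_bundle.truth.planted_pairs]
    pm2 = small_pairmatrix.loc[planted[:2]]
    res = lasso_cox_cv(pm2, t, e, penalty=1e-6)
    ref = cox_fit(pm2.T, t, e, tie_method="breslow")
    for p in planted[:2]:
        assert res["coef"][p] == pytest.approx(ref.table.loc[p, "coef"], abs=1e-3)


def test_lasso_needs_enough_events():
    rng = np.random.default_rng(0)
    pm = pd.DataFrame(rng.integers(0, 2, (3, 30)), index=list("abc"))
    t = rng.uniform(1, 100, 30)
    e = np.zeros(30, int)
    e[:5] = 1
    with pytest.raises(ValueError):
        lasso_cox_cv(pm, t, e, folds=10)


# ---------------------------------------------------------------------------
# stepwise
# ---------------------------------------------------------------------------

def test_stepwise_single_survivor_and_aic_improvement(small_bundle, small_pairmatrix):
    t, e = surv_arrays(small_bundle.clinical)
    planted = [pair_id(a, b) for (a, b), _ in small_bundle.truth.planted_pairs]
    single = stepwise_cox(small_pairmatrix.loc[[planted[0]]], t, e)
    assert single.pairs == [planted[0]]
    nulls = [p for p in small_pairmatrix.index if p not in planted][:2]
    sig = stepwise_cox(small_pairmatrix.loc[planted + nulls], t, e)
    assert len(set(sig.pairs) & set(planted)) >= 3
    full = cox_fit(small_pairmatrix.loc[planted + nulls].T, t, e)
    assert sig.fit.aic <= full.aic + 1e-9


def test_risk_score_exact_linear_combination(small_bundle, small_pairmatrix):
    t, e = surv_arrays(small_bundle.clinical)
    sig = build_signature(small_pairmatrix, t, e, seed=0)
    scores = risk_scores(sig, small_pairmatrix)
    manual = sum(sig.coef[p] * small_pairmatrix.loc[p] for p in sig.pairs)
    assert np.allclose(scores.to_numpy(), manual.to_numpy())
    with pytest.raises(KeyError):
        risk_scores(sig, small_pairmatrix.drop(index=sig.pairs[0]))


def test_build_signature_nesting_and_determinism(small_bundle, small_pairmatrix):
    t, e = surv_arrays(small_bundle.clinical)
    s1 = build_signature(small_pairmatrix, t, e, seed=5)
    s2 = build_signature(small_pairmatrix, t, e, seed=5)
    assert s1.pairs == s2.pairs
    assert np.allclose(s1.coef.to_numpy(), s2.coef.to_numpy())
    tr = s1.trace
    assert tr["k_final"] <= tr["k2_lasso"] <= tr["k1_univariate"]
    assert not s1.coef.isna().any()


def test_estimator_facade_matches_functions(small_bundle, small_pairmatrix):
    t, e = surv_arrays(small_bundle.clinical)
    est = PairedCoxSignature(seed=5).fit(
        small_pairmatrix.T, Surv.from_arrays(e.astype(bool), t))
    ref = build_signature(small_pairmatrix, t, e, seed=5)
    assert est.pairs_ == ref.pairs
    assert np.allclose(est.predict(small_pairmatrix.T),
                       risk_scores(ref, small_pairmatrix).to_numpy())
    params = est.get_params()
    assert params["seed"] == 5


# ---------------------------------------------------------------------------
# expression baseline
# ---------------------------------------------------------------------------

def test_baseline_expression_signature_median_split(rng):
    # planted expression-prognostic gene: hazard grows with expression
    n = 300
    x = rng.normal(5, 1, n)
    t = rng.exponential(1000 / np.exp(0.8 * (x - 5))) + 1
    e = (rng.uniform(size=n) < 0.75).astype(int)
    expr = pd.DataFrame(
        np.vstack([np.exp2(x), rng.lognormal(3, 1, (4, n))]),
        index=["PROG", "N1", "N2", "N3", "N4"],
        columns=[f"S{i}" for i in range(n)])
    sig = baseline_expression_signature(expr, t, e)
    assert "PROG" in sig.genes
    assert sig.coef["PROG"] > 0
    groups = sig.groups(expr)
    assert abs((groups == "high").sum() - (groups == "low").sum()) <= 1


def test_baseline_no_gene_passing_raises(rng):
    n = 100
    expr = pd.DataFrame(rng.lognormal(3, 1, (3, n)), index=["A", "B", "C"],
                        columns=[f"S{i}" for i in range(n)])
    t = rng.exponential(500, n) + 1
    e = np.ones(n, int)
    with pytest.raises(RuntimeError):
        baseline_expression_signature(expr, t, e, p_threshold=1e-9)
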