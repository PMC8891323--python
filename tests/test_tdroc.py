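"""Time-dependent ROC and AIC cutoff selection."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import irlncpair as ip
from irlncpair.roc import RiskStratifier, aic_cutoff, assign_groups, td_roc
from irlncpair.stats import cox1


def _mw_auc(scores, positive):
    """Brute-force Mann–Whitney AUC with half-credit ties."""
    pos, neg = scores[positive], scores[~positive]
    total = 0.0
    for p in pos:
        for n in neg:
            total += (p > n) + 0.5 * (p == n)
    return total / (len(pos) * len(neg))


@pytest.mark.parametrize("seed", range(10))
def test_no_censoring_reduces_to_empirical_roc(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(20, 60))
    scores = rng.normal(size=n)
    times = rng.uniform(1, 100, n)
    events = np.ones(n, int)
    horizon = float(np.quantile(times, 0.5))
    roc = td_roc(scores, times, events, horizon)
    positive = times <= horizon
    assert roc.auc == pytest.approx(_mw_auc(scores, positive), abs=1e-10)


def test_null_score_auc_near_half(rng):
    n = 2000
    scores = rng.normal(size=n)
    times = rng.exponential(500, n) + 1
    events = (rng.uniform(size=n) < 0.7).astype(int)
    roc = td_roc(scores, times, events, 365)
    assert roc.auc == pytest.approx(0.5, abs=0.05)


def test_perfect_separation_auc_one(rng):
    n = 100
    scores = np.arange(n, dtype=float)
    times = np.where(scores >= 50, 10.0, 1000.0) + rng.uniform(0, 1, n)
    events = np.ones(n, int)
    assert td_roc(scores, times, events, 365).auc == pytest.approx(1.0)


def test_auc_invariant_under_monotone_transform(rng):
    n = 150
    scores = rng.normal(size=n)
    times = rng.exponential(300 / np.exp(scores), n) + 1
    events = (rng.uniform(size=n) < 0.8).astype(int)
    a1 = td_roc(scores, times, events, 200).auc
    a2 = td_roc(np.exp(3 * scores) + 7, times, events, 200).auc
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_td_roc_input_validation(rng):
    t = rng.uniform(100, 400, 20)
    with pytest.raises(ValueError):
        td_roc(rng.normal(size=20), t, np.ones(20, int), 1e6)
    with pytest.raises(ValueError):
        td_roc(rng.normal(size=20), t + 500, np.zeros(20, int), 365)


# ---------------------------------------------------------------------------
# AIC cutoff
# ---------------------------------------------------------------------------

def _efron_loglik_binary(beta, z, time, event):
    ll = 0.0
    for tt in np.unique(time[event == 1]):
        D = np.where((time == tt) & (event == 1))[0]
        R = np.where(time >= tt)[0]
        d = len(D)
        wD = np.exp(beta * z[D]).sum()
        ll += beta * z[D].sum()
        for l in range(d):
            ll -= np.log(np.exp(beta * z[R]).sum() - (l / d) * wD)
    return ll


def _brute_force_cutoff(scores, times, events):
    """Independent scan: per candidate, maximize the partial likelihood directly.

    Candidates with monotone likelihood (optimum running to the boundary) are
    non-identified and excluded, matching the flagged-fit contract.
    """
    uniq = np.unique(scores)
    best = (np.inf, None)
    for c in (uniq[:-1] + uniq[1:]) / 2:
        z = (scores > c).astype(float)
        opt = minimize_scalar(lambda b: -_efron_loglik_binary(b, z, times, events),
                              bounds=(-12, 12), method="bounded",
                              options={"xatol": 1e-9})
        if abs(opt.x) > 8:
            continue
        aic = 2 + 2 * opt.fun
        if aic < best[0] - 1e-12:
            best = (aic, c)
    return best


@pytest.mark.parametrize("seed", range(8))
def test_aic_cutoff_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(15, 40))
    scores = rng.normal(size=n)
    times = rng.exponential(200 / np.exp(scores), n).round(1) + 1
    events = (rng.uniform(size=n) < 0.8).astype(int)
    if events.sum() < 3 or not ((times <= 150) & (events == 1)).any():
        pytest.skip("degenerate draw")
    res = aic_cutoff(scores, times, events, horizon=150)
    aic_star, c_star = _brute_force_cutoff(scores, times, events)
    assert res.cutoff == pytest.approx(c_star)
    assert res.table["aic"].min() == pytest.approx(aic_star, abs=1e-5)


def test_two_distinct_scores_single_midpoint(rng):
    scores = np.repeat([0.0, 1.0], 15)
    times = rng.exponential(np.where(scores > 0.5, 50, 500)) + 1
    events = np.ones(30, int)
    res = aic_cutoff(scores, times, events, horizon=100)
    assert res.cutoff == pytest.approx(0.5)
    with pytest.raises(ValueError):
        aic_cutoff(np.zeros(30), times, events, horizon=100)


def test_bimodal_cutoff_in_gap_and_methods_agree(rng):
    # cleanly separated bimodal risk: tight modes, strong hazard jump
    lo = rng.normal(0, 0.2, 100)
    hi = rng.normal(4, 0.2, 100)
    scores = np.concatenate([lo, hi])
    times = np.concatenate([rng.exponential(4000, 100), rng.exponential(80, 100)]) + 1
    events = np.ones(200, int)
    res_aic = aic_cutoff(scores, times, events, horizon=365, method="aic")
    res_youden = aic_cutoff(scores, times, events, horizon=365, method="youden")
    gap = (lo.max(), hi.min())
    assert gap[0] < res_aic.cutoff < gap[1]
    assert gap[0] < res_youden.cutoff < gap[1]


def test_assign_groups_boundary_strict():
    g = assign_groups(np.array([-1.0, 0.0, 0.5]), 0.0)
    assert list(g) == ["low", "low", "high"]
    with pytest.raises(ValueError):
        assign_groups(np.array([1.0]), np.inf)


def test_stratifier_reuses_training_cutoff(rng):
    n = 200
    scores = rng.normal(size=n)
    times = rng.exponential(500 / np.exp(scores), n) + 1
    events = (rng.uniform(size=n) < 0.8).astype(int)
    strat = RiskStratifier(horizon=200).fit(scores[:100], times[:100], events[:100])
    cut = strat.cutoff_
    g = strat.predict(scores[100:])
    assert strat.cutoff_ == cut                  # no re-estimation on new data
    assert set(g) <= {"high", "low"}
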