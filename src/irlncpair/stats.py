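"""Shared survival and association statistics.

Everything downstream of screening reduces to a handful of primitives:
Kaplan–Meier product-limit curves, the log-rank test, Cox proportional-hazards
fits (Efron tie handling by default), Benjamini–Hochberg FDR, and the usual
correlation / rank / chi-square tests.  Standard fits are delegated to
lifelines / statsmodels / scipy; a fast single-covariate Newton solver
(:func:`cox1`) is provided for the large univariate scans where per-fit
overhead dominates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "KMCurve",
    "SurvivalFit",
    "km_curve",
    "logrank_test",
    "cox_fit",
    "cox1",
    "bh_fdr",
    "pearson_test",
    "spearman_test",
    "ranksum_test",
    "kruskal_test",
    "chisq_test",
]


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate with risk/event counts at each event time."""

    times: np.ndarray        # distinct observed times (ascending)
    survival: np.ndarray     # S(t) evaluated at ``times`` (right-continuous)
    at_risk: np.ndarray      # number at risk just before each time
    n_events: np.ndarray     # events at each time

    def evaluate(self, t: float) -> float:
        """S(t) for an arbitrary time (step function, S(0)=1)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def _check_surv(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty survival input")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("event indicators must be 0/1")
    return times, events.astype(int)


def km_curve(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimator."""
    times, events = _check_surv(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
    t = tab.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(t).to_numpy()
    return KMCurve(times=t, survival=surv,
                   at_risk=tab["at_risk"].to_numpy(),
                   n_events=tab["observed"].to_numpy())


def km_survival_at(times, events, horizon: float) -> float:
    """S(horizon) by a direct product-limit computation (no fitting overhead)."""
    times, events = _check_surv(times, events)
    order = np.argsort(times, kind="mergesort")
    t, e = times[order], events[order]
    s = 1.0
    i, n = 0, len(t)
    while i < n and t[i] <= horizon:
        j = i
        d = 0
        while j < n and t[j] == t[i]:
            d += e[j]
            j += 1
        if d:
            s *= 1.0 - d / (n - i)
        i = j
    return s


def logrank_test(groups, times, events):
    """Log-rank test across two or more groups.

    Returns ``(chi2, df, p)``; df = (#groups − 1).
    """
    times, events = _check_surv(times, events)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("log-rank test needs at least two groups")
    if any((groups == g).sum() == 0 for g in labels):  # pragma: no cover
        raise ValueError("empty group")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), len(labels) - 1, float(res.p_value)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class SurvivalFit:
    """Result of a Cox fit: per-covariate table plus model-level diagnostics.

    ``table`` columns: coef, se, hr, ci_low, ci_high, p.
    AIC = 2k − 2·log partial likelihood.
    """

    table: pd.DataFrame
    log_likelihood: float
    aic: float
    n: int
    n_events: int
    converged: bool = True
    messages: list = field(default_factory=list)

    @property
    def coef(self) -> pd.Series:
        return self.table["coef"]


def _efron_derivs_multi(X, beta, times, events):
    """Efron log partial likelihood, gradient and Hessian (p covariates).

    ``X`` must be sorted by ascending time along axis 0.
    """
    eta = np.clip(X @ beta, -500, 500)
    w = np.exp(eta)
    WX = w[:, None] * X
    WXX = np.einsum("i,ij,ik->ijk", w, X, X)
    S0 = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
    S1 = np.concatenate([np.cumsum(WX[::-1], axis=0)[::-1],
                         np.zeros((1, X.shape[1]))])
    S2 = np.concatenate([np.cumsum(WXX[::-1], axis=0)[::-1],
                         np.zeros((1, X.shape[1], X.shape[1]))])
    ll = 0.0
    grad = np.zeros(X.shape[1])
    hess = np.zeros((X.shape[1], X.shape[1]))
    n, i = len(times), 0
    while i < n:
        j = i
        while j < n and times[j] == times[i]:
            j += 1
        D = [k for k in range(i, j) if events[k] == 1]
        d = len(D)
        if d:
            s0d, s1d, s2d = w[D].sum(), WX[D].sum(0), WXX[D].sum(0)
            ll += eta[D].sum()
            grad += X[D].sum(0)
            for l in range(d):
                c = l / d
                s0 = S0[i] - c * s0d
                s1 = S1[i] - c * s1d
                s2 = S2[i] - c * s2d
                ll -= np.log(s0)
                mu = s1 / s0
                grad -= mu
                hess -= s2 / s0 - np.outer(mu, mu)
        i = j
    return ll, grad, hess


def _newton_polish(X, beta0, times, events, max_iter=30, tol=1e-11):
    """Refine a Cox solution to machine precision by full Newton steps."""
    order = np.argsort(times, kind="mergesort")
    Xs, ts, es = X[order], times[order], events[order]
    beta = beta0.copy()
    for _ in range(max_iter):
        ll, grad, hess = _efron_derivs_multi(Xs, beta, ts, es)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta0, None
        if not np.isfinite(step).all() or np.linalg.norm(step) > 1.0:
            return beta0, None       # would leave lifelines' basin; keep its answer
        beta = beta - step
        if np.linalg.norm(step) < tol:
            break
    ll, grad, hess = _efron_derivs_multi(Xs, beta, ts, es)
    return beta, (ll, hess)


def cox_fit(X: pd.DataFrame, times, events, tie_method: str = "efron",
            allow_constant: bool = False, robust: bool = False) -> SurvivalFit:
    """Multivariate Cox PH fit (lifelines backend, Efron ties by default).

    Non-convergence (monotone likelihood / separation) yields a flagged fit
    (``converged=False``) rather than silent numbers.
    """
    times, events = _check_surv(times, events)
    X = pd.DataFrame(X)
    if not allow_constant:
        const = [c for c in X.columns if X[c].nunique() <= 1]
        if const:
            raise ValueError(f"constant covariate(s): {const}")
    df = X.copy()
    df["_time"], df["_event"] = times, events
    cph = CoxPHFitter()
    messages, converged = [], True
    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="_time", event_col="_event",
                    fit_options={"precision": 1e-9, "max_steps": 500})
        except ConvergenceError as exc:
            return SurvivalFit(
                table=pd.DataFrame(np.nan, index=X.columns,
                                   columns=["coef", "se", "hr", "ci_low", "ci_high", "p"]),
                log_likelihood=np.nan, aic=np.nan, n=len(times),
                n_events=int(events.sum()), converged=False,
                messages=[str(exc)])
        for w in wrec:
            msg = str(w.message)
            messages.append(msg)
            if "convergence" in msg.lower() or "collinear" in msg.lower():
                converged = False
    s = cph.summary
    coef = s["coef"].to_numpy()
    se = s["se(coef)"].to_numpy()
    ll = float(cph.log_likelihood_)
    # lifelines stops on a soft criterion; polish to the exact optimum
    beta, extra = _newton_polish(X.to_numpy(dtype=float), coef, times, events)
    if extra is not None:
        ll, hess = extra
        try:
            cov = np.linalg.inv(-hess)
            se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            beta = coef
        coef = beta
    z = coef / se
    pvals = 2 * sps.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):
        table = pd.DataFrame({
            "coef": coef,
            "se": se,
            "hr": np.exp(coef),
            "ci_low": np.exp(coef - 1.959963984540054 * se),
            "ci_high": np.exp(coef + 1.959963984540054 * se),
            "p": pvals,
        }, index=list(X.columns))
    k = X.shape[1]
    return SurvivalFit(table=table, log_likelihood=ll, aic=2 * k - 2 * ll,
                       n=len(times), n_events=int(events.sum()),
                       converged=converged, messages=messages)


def _efron_derivs(x, eta, time, event, beta):
    """Log partial likelihood, gradient and Hessian for one covariate (Efron)."""
    w = np.exp(np.clip(eta, -500, 500))
    wx, wx2 = w * x, w * x * x
    # suffix sums over samples sorted by ascending time
    S0 = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
    S1 = np.concatenate([np.cumsum(wx[::-1])[::-1], [0.0]])
    S2 = np.concatenate([np.cumsum(wx2[::-1])[::-1], [0.0]])
    ll = grad = hess = 0.0
    n = len(time)
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        D = [k for k in range(i, j) if event[k] == 1]
        d = len(D)
        if d:
            s0d = w[D].sum()
            s1d = wx[D].sum()
            s2d = wx2[D].sum()
            ll += eta[D].sum()
            grad += x[D].sum()
            for l in range(d):
                c = l / d
                s0 = S0[i] - c * s0d
                s1 = S1[i] - c * s1d
                s2 = S2[i] - c * s2d
                ll -= np.log(s0)
                mu = s1 / s0
                grad -= mu
                hess -= s2 / s0 - mu * mu
        i = j
    return ll, grad, hess


def cox1(x, times, events, max_iter: int = 60, tol: float = 1e-10) -> SurvivalFit:
    """Single-covariate Cox fit via Newton–Raphson on the Efron partial likelihood.

    Orders of magnitude faster than a general fitter for the univariate pair
    scans; agrees with :func:`cox_fit` (checked in the test suite).
    """
    times, events = _check_surv(times, events)
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant covariate")
    order = np.argsort(times, kind="mergesort")
    xs, ts, es = x[order], times[order], events[order]
    beta, converged = 0.0, False
    ll = grad = hess = np.nan
    for _ in range(max_iter):
        ll, grad, hess = _efron_derivs(xs, beta * xs, ts, es, beta)
        if hess >= 0 or not np.isfinite(hess):
            break
        step = grad / (-hess)
        step = np.clip(step, -5.0, 5.0)
        beta += step
        if abs(beta) > 30:   # monotone likelihood / separation
            break
        if abs(step) < tol:
            converged = True
            break
    ll, grad, hess = _efron_derivs(xs, beta * xs, ts, es, beta)
    info = -hess
    se = 1.0 / np.sqrt(info) if info > 0 else np.nan
    z = beta / se if se and np.isfinite(se) else np.nan
    p = 2 * sps.norm.sf(abs(z)) if np.isfinite(z) else np.nan
    with np.errstate(over="ignore"):
        table = pd.DataFrame(
            {"coef": [beta], "se": [se], "hr": [np.exp(beta)],
             "ci_low": [np.exp(beta - 1.959963984540054 * se)],
             "ci_high": [np.exp(beta + 1.959963984540054 * se)],
             "p": [p]}, index=["x"])
    return SurvivalFit(table=table, log_likelihood=float(ll), aic=2 - 2 * float(ll),
                       n=len(times), n_events=int(es.sum()), converged=converged)


def breslow_loglik(X, beta, times, events) -> float:
    """Breslow log partial likelihood for an arbitrary coefficient vector.

    Used to score held-out folds when tuning the Lasso-Cox penalty (the
    elastic-net path solver itself optimizes the Breslow likelihood).
    """
    times, events = _check_surv(times, events)
    X = np.asarray(X, dtype=float)
    eta = X @ np.asarray(beta, dtype=float)
    order = np.argsort(times, kind="mergesort")
    eta, ts, es = eta[order], times[order], events[order]
    m = eta.max()
    S0 = np.concatenate([np.cumsum(np.exp(eta - m)[::-1])[::-1], [0.0]])
    ll = 0.0
    n, i = len(ts), 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        d = int(es[i:j].sum())
        if d:
            ll += eta[i:j][es[i:j] == 1].sum() - d * (np.log(S0[i]) + m)
        i = j
    return float(ll)


# ---------------------------------------------------------------------------
# Multiple testing and plain association tests
# ---------------------------------------------------------------------------

def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (NaNs propagate)."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if (p[ok] < 0).any() or (p[ok] > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _finite_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def pearson_test(x, y, exact: bool = False):
    """Pearson correlation with t-approximation p (permutation p if ``exact``)."""
    x, y = _finite_pairs(x, y)
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    method = sps.PermutationMethod(n_resamples=9999, rng=0) if exact else None
    res = sps.pearsonr(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


def spearman_test(x, y):
    """Spearman rank correlation (mid-ranks for ties, large-sample p)."""
    x, y = _finite_pairs(x, y)
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def ranksum_test(a, b):
    """Two-sample Mann–Whitney/Wilcoxon rank-sum test (two-sided, tie-corrected)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def kruskal_test(groups):
    """Kruskal–Wallis H test over a list of samples."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[np.isfinite(g)] for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >=2 non-empty groups")
    if all(len(np.unique(np.concatenate(groups))) == 1 for _ in (0,)):
        return 0.0, 1.0
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def chisq_test(table, correction: bool = False):
    """Chi-square test of independence (no Yates correction by default)."""
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise ValueError("negative counts")
    res = sps.chi2_contingency(table, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)
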