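"""Time-dependent ROC, AUC, and risk-score dichotomization.

The ROC estimator is the Kaplan–Meier method of Heagerty, Lumley & Pepe:
with S(t) the overall KM curve and S(t | X > c) the KM curve within samples
scoring above the cutoff,

    Se(c, t) = [1 − S(t | X > c)] · P(X > c) / [1 − S(t)]
    Sp(c, t) =      S(t | X ≤ c) · P(X ≤ c) /      S(t)

estimates are clipped to [0, 1] and the AUC is the trapezoid over the sorted
(1 − Sp, Se) polyline.  Without censoring before the horizon this reduces
exactly to the empirical ROC of score vs event-by-horizon status.

The dichotomization cutoff is chosen by scanning every candidate (midpoints
between consecutive sorted unique scores), refitting a one-covariate Cox
model on indicator(score > c) over the full follow-up, and minimizing its
AIC = 2 − 2·logPL; the Youden-optimal ROC point at the horizon is available
as an alternative rule.  The training-set cutoff is reused unchanged on test
and entire sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import cox1, km_survival_at

DEFAULT_HORIZONS = (365, 1095, 1825)   # 1, 3 and 5 years, in days


@dataclass
class TdRoc:
    horizon: float
    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"cutoff": self.cutoffs, "sensitivity": self.sensitivity,
                             "specificity": self.specificity})


@dataclass
class CutoffResult:
    cutoff: float
    method: str
    table: pd.DataFrame     # per candidate: cutoff, aic, sensitivity, specificity, youden


def _se_sp_at(scores, times, events, c, horizon, s_marg):
    """KM-method (Se, Sp) at cutoff c and the horizon."""
    above = scores > c
    p_above = above.mean()
    f_marg = 1.0 - s_marg
    if above.any():
        s_above = km_survival_at(times[above], events[above], horizon)
        se = (1.0 - s_above) * p_above / f_marg if f_marg > 0 else np.nan
    else:
        se = 0.0
    if (~above).any():
        s_below = km_survival_at(times[~above], events[~above], horizon)
        sp = s_below * (1.0 - p_above) / s_marg if s_marg > 0 else np.nan
    else:
        sp = 0.0
    # snap to 12 decimals: float jitter must not disorder the ROC staircase
    return (float(np.round(np.clip(se, 0, 1), 12)),
            float(np.round(np.clip(sp, 0, 1), 12)))


def td_roc(scores, times, events, horizon: float) -> TdRoc:
    """Kaplan–Meier time-dependent ROC for predicting event by ``horizon``."""
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if horizon > times.max():
        raise ValueError("horizon beyond observed follow-up")
    if not ((times <= horizon) & (events == 1)).any():
        raise ValueError("no events observed before the horizon")
    s_marg = km_survival_at(times, events, horizon)
    cutoffs = np.unique(scores)
    se = np.empty(len(cutoffs))
    sp = np.empty(len(cutoffs))
    for i, c in enumerate(cutoffs):
        se[i], sp[i] = _se_sp_at(scores, times, events, c, horizon, s_marg)
    # assemble polyline with the (0,0)/(1,1) endpoints, sort by FPR then TPR
    x = np.concatenate([[0.0], 1.0 - sp, [1.0]])
    y = np.concatenate([[0.0], se, [1.0]])
    order = np.lexsort((y, x))
    auc = float(np.trapezoid(y[order], x[order]))
    return TdRoc(horizon=float(horizon), cutoffs=cutoffs, sensitivity=se,
                 specificity=sp, auc=auc)


def aic_cutoff(scores, times, events, horizon: float,
               method: str = "aic") -> CutoffResult:
    """Choose the risk-group cutoff from the ROC candidate grid.

    Candidates are midpoints between consecutive sorted unique scores; each is
    scored by the AIC of a univariate Cox fit on indicator(score > c) over the
    full follow-up (``method="aic"``, minimized) or by Youden's J at the
    horizon (``method="youden"``, maximized).  Candidates whose dichotomized
    Cox fit is non-identified (monotone likelihood, e.g. an extreme cutoff
    isolating a censored-only group) are excluded from the AIC rule.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    uniq = np.unique(scores)
    if len(uniq) < 2:
        raise ValueError("need at least 2 distinct scores")
    if method not in ("aic", "youden"):
        raise ValueError(f"unknown method {method!r}")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    s_marg = km_survival_at(times, events, horizon)
    rows = []
    for c in candidates:
        z = (scores > c).astype(float)
        fit = cox1(z, times, events)
        aic = fit.aic if fit.converged else np.nan
        se, sp = _se_sp_at(scores, times, events, c, horizon, s_marg)
        rows.append((float(c), aic, se, sp, se + sp - 1.0))
    tab = pd.DataFrame(rows, columns=["cutoff", "aic", "sensitivity",
                                      "specificity", "youden"])
    if method == "aic":
        if tab["aic"].isna().all():
            raise ValueError("no candidate produced a converging Cox fit")
        best = int(tab["aic"].idxmin())
    else:
        best = int(tab["youden"].idxmax())
    return CutoffResult(cutoff=float(tab.loc[best, "cutoff"]), method=method, table=tab)


def assign_groups(scores, cutoff: float) -> pd.Series | np.ndarray:
    """score > cutoff -> "high", else "low" (boundary scores are low)."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    if isinstance(scores, pd.Series):
        return pd.Series(np.where(scores > cutoff, "high", "low"),
                         index=scores.index, name="group")
    return np.where(np.asarray(scores, dtype=float) > cutoff, "high", "low")


class RiskStratifier:
    """Fit the AIC cutoff on training scores; reuse it unchanged elsewhere.

    Mirrors the study protocol: the cutoff is estimated once, on the training
    set's 1-year ROC candidates, and applied verbatim to test/entire sets.
    """

    def __init__(self, horizon: float = 365.0, method: str = "aic"):
        self.horizon = horizon
        self.method = method

    def fit(self, scores, times, events):
        res = aic_cutoff(scores, times, events, self.horizon, method=self.method)
        self.cutoff_ = res.cutoff
        self.candidates_ = res.table
        return self

    def predict(self, scores):
        if not hasattr(self, "cutoff_"):
            raise RuntimeError("RiskStratifier is not fitted")
        return assign_groups(scores, self.cutoff_)
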