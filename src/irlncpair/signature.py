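"""Prognostic pair-signature construction.

Pipeline on the training half of the cohort: univariate Cox screen over all
pair features -> Lasso-penalized Cox with 10-fold cross-validation (penalty
minimizing the Verweij–van Houwelingen CV deviance) -> bidirectional
AIC-stepwise multivariate Cox.  The final signature's risk score is the Cox
linear predictor Risk = sum_i beta_i * S_i over its pairs.  A conventional
expression-level signature (univariate screen at P < 0.001, stepwise Cox on
log2 expression, median-split groups) is provided as a comparison baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .io import log2p1
from .stats import SurvivalFit, breslow_loglik, cox1, cox_fit

log = logging.getLogger("irlncpair")


# ---------------------------------------------------------------------------
# Cohort split
# ---------------------------------------------------------------------------

def split_cohort(clinical: pd.DataFrame, ratio: float = 0.5, seed: int = 0,
                 stratify_on: str = "os_event") -> tuple:
    """Random event-stratified split into (train_ids, test_ids)."""
    if len(clinical) < 20:
        raise ValueError("need at least 20 samples to split")
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0,1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for _, grp in clinical.groupby(stratify_on, sort=True):
        ids = grp["sample_id"].to_numpy()
        ids = ids[rng.permutation(len(ids))]
        k = int(round(ratio * len(ids)))
        train.extend(ids[:k])
        test.extend(ids[k:])
    if min(len(train), len(test)) == 0:
        raise ValueError("degenerate split; too few samples in a stratum")
    return sorted(train), sorted(test)


# ---------------------------------------------------------------------------
# Univariate screen
# ---------------------------------------------------------------------------

def univariate_screen(pm: pd.DataFrame, times, events,
                      p_threshold: float = 0.05) -> pd.DataFrame:
    """Per-pair single-covariate Cox fits; returns the full table.

    Columns: coef, se, hr, p, aic, selected.  Pairs constant within the
    training samples are skipped (logged).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    rows, skipped = [], 0
    for pid, s in pm.iterrows():
        x = s.to_numpy(dtype=float)
        if np.ptp(x) == 0:
            skipped += 1
            continue
        fit = cox1(x, times, events)
        t = fit.table.iloc[0]
        rows.append((pid, t["coef"], t["se"], t["hr"], t["p"], fit.aic, fit.converged))
    if skipped:
        log.warning("univariate_screen: skipped %d constant pair(s)", skipped)
    out = pd.DataFrame(rows, columns=["pair", "coef", "se", "hr", "p", "aic",
                                      "converged"]).set_index("pair")
    out["selected"] = (out["p"] < p_threshold) & out["converged"]
    return out


# ---------------------------------------------------------------------------
# Lasso-Cox with cross-validation
# ---------------------------------------------------------------------------

def lasso_cox_cv(pm: pd.DataFrame, times, events, folds: int = 10, seed: int = 0,
                 penalty: float | None = None, alphas=None,
                 n_alphas: int = 50) -> dict:
    """Lasso-penalized Cox over candidate pairs with seeded K-fold CV.

    The penalty path comes from the elastic-net solver (l1 ratio 1); each
    held-out fold is scored by the Verweij–van Houwelingen partial-likelihood
    deviance −2·[logPL_all(β_train) − logPL_train(β_train)] and the
    deviance-minimizing penalty is chosen.  Returns a dict with ``survivors``
    (pair ids with nonzero coefficients), ``coef`` (their Lasso coefficients),
    ``penalty`` and the CV table.  If nothing survives, an empty survivor list
    is returned with a warning.
    """
    if len(pm) < 2:
        raise ValueError("need at least 2 candidate pairs")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < folds:
        raise ValueError("fewer events than CV folds")
    X = pm.T.to_numpy(dtype=float)
    y = Surv.from_arrays(events.astype(bool), times)

    def _fit(Xf, yf, alphas_):
        est = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas_,
                                     alpha_min_ratio=0.01, n_alphas=n_alphas,
                                     fit_baseline_model=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(Xf, yf)
        return est

    if penalty is not None:
        est = _fit(X, y, [penalty])
        coefs = est.coef_[:, 0]
        survivors = [p for p, c in zip(pm.index, coefs) if abs(c) > 1e-10]
        return {"survivors": survivors,
                "coef": pd.Series(coefs, index=pm.index).loc[survivors],
                "penalty": float(penalty), "cv": None}

    full = _fit(X, y, alphas)
    path = np.asarray(full.alphas_)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.full((folds, len(path)), np.nan)
    for f, (tr, _) in enumerate(kf.split(X)):
        est = _fit(X[tr], y[tr], list(path))
        # the solver may drop path points it cannot reach on this fold
        cols = {round(float(a), 12): i for i, a in enumerate(est.alphas_)}
        B = est.coef_                      # (n_features, n_kept_alphas)
        for a, alpha in enumerate(path):
            i = cols.get(round(float(alpha), 12))
            if i is None:
                continue
            ll_all = breslow_loglik(X, B[:, i], times, events)
            ll_tr = breslow_loglik(X[tr], B[:, i], times[tr], events[tr])
            dev[f, a] = -2.0 * (ll_all - ll_tr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")    # all-NaN path points
        mean_dev = np.nanmean(dev, axis=0)
    if not np.isfinite(mean_dev).any():
        raise RuntimeError("cross-validation failed for every penalty")
    best = int(np.nanargmin(mean_dev))
    coefs = full.coef_[:, best]
    survivors = [p for p, c in zip(pm.index, coefs) if abs(c) > 1e-10]
    if not survivors:
        log.warning("lasso_cox_cv: all coefficients zero at the CV-optimal penalty")
    cv = pd.DataFrame({"penalty": path, "mean_deviance": mean_dev})
    return {"survivors": survivors,
            "coef": pd.Series(coefs, index=pm.index).loc[survivors],
            "penalty": float(path[best]), "cv": cv}


# ---------------------------------------------------------------------------
# Stepwise multivariate Cox
# ---------------------------------------------------------------------------

def _try_cox(pm: pd.DataFrame, cols, times, events) -> SurvivalFit | None:
    try:
        fit = cox_fit(pm.loc[list(cols)].T, times, events)
    except Exception as exc:   # any failed fit simply makes the move invalid
        log.debug("stepwise candidate %s failed: %s", cols, exc)
        return None
    if not np.isfinite(fit.aic) or not fit.converged:
        return None
    return fit


@dataclass
class PairSignature:
    pairs: list
    coef: pd.Series
    fit: SurvivalFit
    train_ids: list
    trace: dict = field(default_factory=dict)     # k1 univariate, k2 lasso, k final
    lasso_pairs: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"pairs": list(self.pairs),
                "coef": {p: float(self.coef[p]) for p in self.pairs},
                "train_ids": list(self.train_ids),
                "trace": {k: (int(v) if isinstance(v, (int, np.integer)) else float(v))
                          for k, v in self.trace.items()},
                "aic": float(self.fit.aic)}


def stepwise_cox(pm: pd.DataFrame, times, events, direction: str = "both") -> PairSignature:
    """Bidirectional AIC-stepwise Cox starting from the full survivor model.

    At each step the drop/add move with the lowest AIC is accepted while it
    improves on the current model; accepted AIC is non-increasing.  If the
    full starting model does not converge, covariates are pruned by weakest
    univariate association until it does.
    """
    pool = list(pm.index)
    if not pool:
        raise ValueError("no survivor pairs")
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)

    current = list(pool)
    fit = _try_cox(pm, current, times, events)
    while fit is None and len(current) > 1:
        # prune weakest univariate pair and retry
        pvals = {}
        for c in current:
            try:
                pvals[c] = cox1(pm.loc[c].to_numpy(), times, events).table["p"].iloc[0]
            except ValueError:
                pvals[c] = 2.0

        worst = max(pvals, key=lambda c: (np.nan_to_num(pvals[c], nan=2.0)))
        log.warning("stepwise_cox: dropping non-converging covariate %s", worst)
        current.remove(worst)
        fit = _try_cox(pm, current, times, events)
    if fit is None:
        raise RuntimeError("no converging Cox model over survivor pairs")

    improved = True
    while improved:
        improved = False
        moves = []
        if direction in ("both", "backward") and len(current) > 1:
            moves += [("drop", c) for c in current]
        if direction in ("both", "forward"):
            moves += [("add", c) for c in pool if c not in current]
        best = (fit.aic, None, None)
        for kind, c in moves:
            cols = [x for x in current if x != c] if kind == "drop" else current + [c]
            cand = _try_cox(pm, cols, times, events)
            if cand is not None and cand.aic < best[0] - 1e-9:
                best = (cand.aic, cols, cand)
        if best[1] is not None:
            current, fit = best[1], best[2]
            improved = True

    coef = fit.table["coef"]
    return PairSignature(pairs=list(current), coef=coef, fit=fit, train_ids=[],
                         trace={})


def risk_scores(sig: PairSignature, pm: pd.DataFrame) -> pd.Series:
    """Risk = sum_i beta_i * S_i for every sample column of ``pm``."""
    missing = [p for p in sig.pairs if p not in pm.index]
    if missing:
        raise KeyError(f"pair(s) missing from pair matrix: {missing}")
    beta = sig.coef.loc[sig.pairs]
    scores = beta.to_numpy() @ pm.loc[sig.pairs].to_numpy(dtype=float)
    return pd.Series(scores, index=pm.columns, name="risk_score")


def build_signature(pm: pd.DataFrame, times, events, univariate_p: float = 0.05,
                    folds: int = 10, seed: int = 0,
                    stepwise_direction: str = "both") -> PairSignature:
    """Full selection cascade on training data; records the selection trace."""
    uni = univariate_screen(pm, times, events, p_threshold=univariate_p)
    cand = list(uni.index[uni["selected"]])
    if not cand:
        raise RuntimeError("no pair passed the univariate screen")
    lasso = lasso_cox_cv(pm.loc[cand], times, events, folds=folds, seed=seed) \
        if len(cand) >= 2 else {"survivors": cand, "penalty": np.nan, "cv": None}
    survivors = lasso["survivors"]
    if not survivors:
        # documented fallback: keep the strongest univariate pairs
        survivors = list(uni.loc[cand].sort_values("p").index[: min(10, len(cand))])
        log.warning("lasso selected nothing; falling back to top %d univariate pairs",
                    len(survivors))
    sig = stepwise_cox(pm.loc[survivors], times, events, direction=stepwise_direction)
    sig.train_ids = list(pm.columns)
    sig.lasso_pairs = list(survivors)
    sig.trace = {"k1_univariate": len(cand), "k2_lasso": len(survivors),
                 "k_final": len(sig.pairs), "lasso_penalty": lasso["penalty"]}
    if not (set(sig.pairs) <= set(survivors) <= set(cand)):
        raise AssertionError("selection nesting violated")
    return sig


# ---------------------------------------------------------------------------
# Expression-level baseline signature
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSignature:
    genes: list
    coef: pd.Series
    fit: SurvivalFit
    median_cutoff: float

    def score(self, expr: pd.DataFrame) -> pd.Series:
        """Risk = sum_i log2-expression_i x coefficient_i."""
        X = log2p1(expr.loc[self.genes])
        return pd.Series(self.coef.loc[self.genes].to_numpy() @ X.to_numpy(),
                         index=expr.columns, name="risk_score")

    def groups(self, expr: pd.DataFrame) -> pd.Series:
        s = self.score(expr)
        return pd.Series(np.where(s > self.median_cutoff, "high", "low"),
                         index=s.index, name="group")


def baseline_expression_signature(expr: pd.DataFrame, times, events,
                                  p_threshold: float = 0.001) -> ExpressionSignature:
    """Conventional per-gene expression signature (training samples).

    Univariate Cox on log2(x+1) expression at P < ``p_threshold``, then
    AIC-stepwise multivariate Cox; risk is the linear predictor over the
    selected genes and groups are split at the training median.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    X = log2p1(expr)
    rows = []
    for g, s in X.iterrows():
        x = s.to_numpy(dtype=float)
        if np.ptp(x) == 0:
            continue
        fit = cox1(x, times, events)
        if fit.converged:
            rows.append((g, fit.table["p"].iloc[0]))
    tab = pd.DataFrame(rows, columns=["gene", "p"]).set_index("gene")
    sel = list(tab.index[tab["p"] < p_threshold])
    if not sel:
        raise RuntimeError(f"no gene passed the P<{p_threshold} screen")
    sig = stepwise_cox(X.loc[sel], times, events)
    scores = sig.coef.loc[sig.pairs].to_numpy() @ X.loc[sig.pairs].to_numpy()
    return ExpressionSignature(genes=list(sig.pairs), coef=sig.coef, fit=sig.fit,
                               median_cutoff=float(np.median(scores)))


# ---------------------------------------------------------------------------
# Sklearn-style estimator facade
# ---------------------------------------------------------------------------

class PairedCoxSignature(BaseEstimator):
    """Sklearn-style estimator over binary pair features.

    ``fit(X, y)`` takes samples x pairs (0/1, e.g. from :class:`PairEncoder`)
    and a structured survival array (sksurv convention) or ``(times, events)``
    tuple; runs univariate screen -> CV Lasso-Cox -> AIC-stepwise Cox.
    ``predict(X)`` returns the risk score (higher = worse prognosis).

    Fitted attributes: ``pairs_``, ``coef_``, ``trace_``, ``signature_``.
    """

    def __init__(self, univariate_p: float = 0.05, folds: int = 10, seed: int = 0,
                 stepwise_direction: str = "both"):
        self.univariate_p = univariate_p
        self.folds = folds
        self.seed = seed
        self.stepwise_direction = stepwise_direction

    @staticmethod
    def _unpack_y(y):
        if isinstance(y, tuple):
            return np.asarray(y[0], float), np.asarray(y[1], int)
        arr = np.asarray(y)
        if arr.dtype.names:                     # sksurv structured array
            ev, tm = arr.dtype.names
            return arr[tm].astype(float), arr[ev].astype(int)
        raise TypeError("y must be (times, events) or a structured survival array")

    def fit(self, X: pd.DataFrame, y):
        times, events = self._unpack_y(y)
        sig = build_signature(X.T, times, events, univariate_p=self.univariate_p,
                              folds=self.folds, seed=self.seed,
                              stepwise_direction=self.stepwise_direction)
        self.signature_ = sig
        self.pairs_ = list(sig.pairs)
        self.coef_ = sig.coef.loc[sig.pairs].to_numpy()
        self.trace_ = dict(sig.trace)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "signature_"):
            raise RuntimeError("PairedCoxSignature is not fitted")
        return risk_scores(self.signature_, X.T).to_numpy()
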