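"""Clinical validation and immune/drug association statistics for risk groups.

Covers: univariate/multivariate Cox with clinical covariates (is the risk
score an independent prognostic factor?), chi-square association of risk
group with clinicopathological traits, AUC comparison of the score against
clinical variables, Spearman correlation of the score with immune-cell
infiltration estimates (lollipop table), and rank-sum comparisons of immune-
checkpoint gene expression and predicted drug IC50 between risk groups.
Raw p-values are the study's filters; BH q-values are reported alongside,
computed within each association family.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, log2p1
from .roc import td_roc
from .stats import bh_fdr, chisq_test, cox_fit, ranksum_test, spearman_test

log = logging.getLogger("irlncpair")

STAGE_ORDER = {"I": 1, "II": 2, "III": 3, "IV": 4}
GRADE_ORDER = {"Low": 0, "High": 1}
DEFAULT_ICI_GENES = ["PDCD1", "CD274", "CTLA4", "LAG3", "HAVCR2", "TIGIT",
                     "IDO1", "PDCD1LG2"]


def _ordinal(series: pd.Series) -> pd.Series:
    """Numeric coding for clinical covariates (stage/grade ordinal, sex binary)."""
    name = series.name
    if pd.api.types.is_numeric_dtype(series):
        return series.astype(float)
    if name == "stage":
        return series.map(STAGE_ORDER).astype(float)
    if name == "grade":
        return series.map(GRADE_ORDER).astype(float)
    if name in ("T", "N", "M"):
        return series.str.extract(r"(\d+)", expand=False).astype(float)
    if name == "sex":
        return series.map({"male": 1, "female": 0}).astype(float)
    raise ValueError(f"cannot encode covariate {name!r}")


def _covariate_frame(scores: pd.Series, clinical: pd.DataFrame, covariates) -> pd.DataFrame:
    clin = clinical.set_index("sample_id")
    common = scores.index.intersection(clin.index)
    df = pd.DataFrame({"risk_score": scores.loc[common]})
    for c in covariates:
        df[c] = _ordinal(clin.loc[common, c])
    df["_time"] = clin.loc[common, "os_days"].astype(float)
    df["_event"] = clin.loc[common, "os_event"].astype(int)
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        log.info("clinical_cox: dropped %d sample(s) with missing covariates", n0 - len(df))
    return df


def clinical_cox(scores: pd.Series, clinical: pd.DataFrame, mode: str = "multi",
                 covariates=("age", "sex", "grade", "stage")) -> pd.DataFrame:
    """Hazard table (HR, 95% CI, p) for the risk score and clinical covariates.

    ``mode="uni"`` fits each variable alone; ``mode="multi"`` fits all jointly
    with the risk score entered continuous.  Duplicated covariate columns are
    rejected (collinearity guard).
    """
    df = _covariate_frame(scores, clinical, covariates)
    X = df.drop(columns=["_time", "_event"])
    arr = X.to_numpy()
    for i in range(arr.shape[1]):
        for j in range(i + 1, arr.shape[1]):
            if np.allclose(arr[:, i], arr[:, j]):
                raise ValueError(f"collinear covariates: {X.columns[i]} and {X.columns[j]}")
    rows = []
    if mode == "uni":
        for c in X.columns:
            fit = cox_fit(X[[c]], df["_time"], df["_event"])
            t = fit.table.iloc[0]
            rows.append((c, t["hr"], t["ci_low"], t["ci_high"], t["p"], fit.converged))
    elif mode == "multi":
        fit = cox_fit(X, df["_time"], df["_event"])
        for c in X.columns:
            t = fit.table.loc[c]
            rows.append((c, t["hr"], t["ci_low"], t["ci_high"], t["p"], fit.converged))
    else:
        raise ValueError("mode must be 'uni' or 'multi'")
    return pd.DataFrame(rows, columns=["variable", "hr", "ci_low", "ci_high",
                                       "p", "converged"])


def risk_group_associations(groups: pd.Series, clinical: pd.DataFrame,
                            traits=("sex", "grade", "stage", "T", "N", "M")) -> pd.DataFrame:
    """Chi-square test of risk group x category for each clinical trait."""
    clin = clinical.set_index("sample_id")
    common = groups.index.intersection(clin.index)
    if groups.loc[common].nunique() < 2:
        raise ValueError("need at least 2 risk groups")
    rows = []
    for trait in traits:
        col = clin.loc[common, trait].dropna()
        if col.nunique() < 2:
            log.warning("risk_group_associations: trait %r has a single category; skipped",
                        trait)
            continue
        tab = pd.crosstab(groups.loc[col.index], col)
        stat, dof, p = chisq_test(tab.to_numpy())
        expected = np.outer(tab.sum(1), tab.sum(0)) / tab.to_numpy().sum()
        rows.append((trait, stat, dof, p, bool((expected < 5).any())))
    out = pd.DataFrame(rows, columns=["trait", "chi2", "df", "p", "low_expected_counts"])
    out["q"] = bh_fdr(out["p"]) if len(out) else []
    return out


def roc_vs_clinical(scores: pd.Series, clinical: pd.DataFrame,
                    horizon: float = 365.0,
                    variables=("age", "sex", "grade", "stage")) -> pd.DataFrame:
    """1-year (by default) td-ROC AUC of the score vs each clinical variable."""
    clin = clinical.set_index("sample_id")
    common = scores.index.intersection(clin.index)
    times = clin.loc[common, "os_days"].astype(float).to_numpy()
    events = clin.loc[common, "os_event"].astype(int).to_numpy()
    rows = [("risk_score", td_roc(scores.loc[common].to_numpy(), times, events, horizon).auc)]
    for v in variables:
        try:
            x = _ordinal(clin.loc[common, v])
        except ValueError:
            log.warning("roc_vs_clinical: cannot encode %r; skipped", v)
            continue
        ok = x.notna().to_numpy()
        if x[ok].nunique() < 2:
            log.warning("roc_vs_clinical: %r is constant; skipped", v)
            continue
        rows.append((v, td_roc(x.to_numpy()[ok], times[ok], events[ok], horizon).auc))
    return pd.DataFrame(rows, columns=["variable", "auc"])


def infiltration_correlation(scores: pd.Series, infiltration: pd.DataFrame,
                             p_threshold: float = 0.05,
                             min_overlap: int = 10) -> pd.DataFrame:
    """Spearman rho of risk score vs infiltration per (cell type, method)."""
    rows = []
    for (ct, method), grp in infiltration.groupby(["cell_type", "method"], sort=True):
        sub = grp.set_index("sample_id")["score"]
        common = scores.index.intersection(sub.index)
        if len(common) < min_overlap:
            log.warning("infiltration_correlation: %s/%s overlap %d < %d; skipped",
                        ct, method, len(common), min_overlap)
            continue
        rho, p = spearman_test(scores.loc[common], sub.loc[common])
        rows.append((ct, method, rho, p))
    out = pd.DataFrame(rows, columns=["cell_type", "method", "rho", "p"])
    out["q"] = bh_fdr(out["p"]) if len(out) else []
    out["significant"] = out["p"] < p_threshold if len(out) else []
    return out


def group_expression_tests(expr: ExpressionMatrix | pd.DataFrame, gene_symbols,
                           groups: pd.Series, annotation: pd.DataFrame | None = None,
                           p_threshold: float = 0.05) -> pd.DataFrame:
    """Rank-sum test of per-gene expression between high and low risk groups.

    ``gene_symbols`` are matched through ``annotation`` when given, else
    treated as row ids of the expression frame.  Direction is the sign of the
    median difference (high − low).
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if annotation is not None:
        sym2id = annotation.set_index("symbol")["gene_id"]
        targets = [(s, sym2id[s]) for s in gene_symbols if s in sym2id.index]
    else:
        targets = [(g, g) for g in gene_symbols]
    X = log2p1(values)
    hi = groups.index[groups == "high"]
    lo = groups.index[groups == "low"]
    if len(hi) == 0 or len(lo) == 0:
        raise ValueError("both risk groups must be non-empty")
    rows = []
    for label, gid in targets:
        if gid not in X.index:
            log.warning("group_expression_tests: gene %s absent; skipped", label)
            continue
        a = X.loc[gid, X.columns.intersection(hi)]
        b = X.loc[gid, X.columns.intersection(lo)]
        stat, p = ranksum_test(a, b)
        rows.append((label, stat, p, float(np.median(a) - np.median(b))))
    out = pd.DataFrame(rows, columns=["gene", "u_stat", "p", "median_diff"])
    out["q"] = bh_fdr(out["p"]) if len(out) else []
    out["significant"] = out["p"] < p_threshold if len(out) else []
    return out


def group_ic50_tests(ic50: pd.DataFrame, groups: pd.Series,
                     p_threshold: float = 0.05) -> pd.DataFrame:
    """Per-drug rank-sum comparison of predicted IC50 between risk groups.

    ``direction`` is "sensitive_in_high" when the high-risk median IC50 is
    lower (more sensitive), "resistant_in_high" otherwise.
    """
    hi = set(groups.index[groups == "high"])
    lo = set(groups.index[groups == "low"])
    if not hi or not lo:
        raise ValueError("both risk groups must be non-empty")
    rows = []
    for drug, grp in ic50.groupby("drug", sort=True):
        sub = grp.set_index("sample_id")["ic50"]
        a = sub.loc[sub.index.intersection(hi)]
        b = sub.loc[sub.index.intersection(lo)]
        if len(a) == 0 or len(b) == 0:
            log.warning("group_ic50_tests: drug %s missing a group; skipped", drug)
            continue
        stat, p = ranksum_test(a, b)
        diff = float(np.median(a) - np.median(b))
        rows.append((drug, stat, p, diff,
                     "sensitive_in_high" if diff < 0 else "resistant_in_high"))
    out = pd.DataFrame(rows, columns=["drug", "u_stat", "p", "median_diff", "direction"])
    out["q"] = bh_fdr(out["p"]) if len(out) else []
    out["significant"] = out["p"] < p_threshold if len(out) else []
    return out
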