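"""Immune-related lncRNA screening.

Two stages: (1) coexpression with immune genes — a lncRNA is immune-related
if some immune mRNA correlates with it at |r| > 0.4 and P < 0.001 (Pearson on
log2(x+1), tumour samples); (2) differential expression between tumour and
normal samples at |log2FC| > 2 with BH-FDR < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ExpressionMatrix, log2p1
from .stats import bh_fdr

log = logging.getLogger("irlncpair")


@dataclass
class ScreenConfig:
    r_threshold: float = 0.4
    corr_p_threshold: float = 0.001
    lfc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    corr_signed: bool = False       # True: require r > threshold (one-sided)
    corr_all_samples: bool = False  # True: correlate over all samples, not just tumour
    moderated: bool = False         # variance-moderated DE t-statistic
    moderation_prior_df: float = 4.0

    def validate(self):
        if not 0 < self.r_threshold < 1:
            raise ValueError("r_threshold must be in (0,1)")
        for name in ("corr_p_threshold", "fdr_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0,1]")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be >= 0")


def _corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(r, -0.9999999999, 0.9999999999)
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return 2 * sps.t.sf(np.abs(t), df=n - 2)


def coexpression_filter(expr: ExpressionMatrix, lnc_ids, immune_ids,
                        config: ScreenConfig | None = None) -> pd.DataFrame:
    """Retain lncRNAs coexpressed with at least one immune gene.

    Returns a frame (lncrna, partner, r, p) with one row per retained lncRNA,
    recording its best immune partner (largest |r| among qualifying partners).
    """
    config = config or ScreenConfig()
    config.validate()
    cols = expr.values.columns if config.corr_all_samples else expr.tumour_samples
    if len(cols) < 3:
        raise ValueError("need at least 3 samples for correlation screening")
    lnc_ids = [g for g in lnc_ids if g in expr.values.index]
    immune_ids = [g for g in immune_ids if g in expr.values.index]
    if not lnc_ids or not immune_ids:
        raise ValueError("empty lncRNA or immune gene set")

    L = log2p1(expr.values.loc[lnc_ids, cols]).to_numpy()
    I = log2p1(expr.values.loc[immune_ids, cols]).to_numpy()
    n = L.shape[1]

    def _standardize(M, names):
        sd = M.std(axis=1, ddof=1)
        keep = sd > 0
        if not keep.all():
            log.warning("coexpression_filter: skipping %d zero-variance gene(s)",
                        int((~keep).sum()))
        Ms = (M[keep] - M[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
        return Ms, [g for g, k in zip(names, keep) if k]

    Ls, lnc_kept = _standardize(L, lnc_ids)
    Is, imm_kept = _standardize(I, immune_ids)
    R = (Ls @ Is.T) / (n - 1)
    P = _corr_pvalues(R, n)
    qual = (R > config.r_threshold) if config.corr_signed else (np.abs(R) > config.r_threshold)
    qual &= P < config.corr_p_threshold

    rows = []
    score = np.where(qual, R if config.corr_signed else np.abs(R), -np.inf)
    best = np.argmax(score, axis=1)
    for i, g in enumerate(lnc_kept):
        if qual[i].any():
            j = best[i]
            rows.append((g, imm_kept[j], float(R[i, j]), float(P[i, j])))
    return pd.DataFrame(rows, columns=["lncrna", "partner", "r", "p"])


def differential_expression(expr: ExpressionMatrix, ir_lnc_ids,
                            config: ScreenConfig | None = None) -> pd.DataFrame:
    """Tumour-vs-normal Welch t-test per lncRNA on log2(x+1).

    log2FC = mean(tumour) − mean(normal); BH adjustment over the tested
    lncRNAs only.  ``direction`` is "up"/"down" iff q < fdr_threshold and
    |log2FC| clears the threshold, else "ns".
    """
    config = config or ScreenConfig()
    config.validate()
    tum, nor = expr.tumour_samples, expr.normal_samples
    if len(tum) < 2 or len(nor) < 2:
        raise ValueError("need at least 2 samples per condition")
    ids = [g for g in ir_lnc_ids if g in expr.values.index]
    if not ids:
        raise ValueError("no testable lncRNAs")
    X_t = log2p1(expr.values.loc[ids, tum]).to_numpy()
    X_n = log2p1(expr.values.loc[ids, nor]).to_numpy()
    m_t, m_n = X_t.mean(axis=1), X_n.mean(axis=1)
    v_t, v_n = X_t.var(axis=1, ddof=1), X_n.var(axis=1, ddof=1)
    n_t, n_n = X_t.shape[1], X_n.shape[1]
    if config.moderated:
        # shrink per-condition variances toward the panel mean (fixed prior df)
        d0 = config.moderation_prior_df
        v_t = (d0 * v_t.mean() + (n_t - 1) * v_t) / (d0 + n_t - 1)
        v_n = (d0 * v_n.mean() + (n_n - 1) * v_n) / (d0 + n_n - 1)
    se2 = v_t / n_t + v_n / n_n
    lfc = m_t - m_n
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(se2)
        df = se2 ** 2 / ((v_t / n_t) ** 2 / (n_t - 1) + (v_n / n_n) ** 2 / (n_n - 1))
    zero = se2 == 0
    t[zero], df[zero] = 0.0, n_t + n_n - 2
    p = 2 * sps.t.sf(np.abs(t), df=df)
    p[zero & (lfc == 0)] = 1.0
    q = bh_fdr(p)
    direction = np.where((q < config.fdr_threshold) & (lfc > config.lfc_threshold), "up",
                np.where((q < config.fdr_threshold) & (lfc < -config.lfc_threshold),
                         "down", "ns"))
    return pd.DataFrame({"lncrna": ids, "log2fc": lfc, "t": t, "p": p, "q": q,
                         "direction": direction})


def de_gene_ids(de: pd.DataFrame) -> list:
    """Ids of lncRNAs called differentially expressed (up or down)."""
    return list(de.loc[de["direction"] != "ns", "lncrna"])
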