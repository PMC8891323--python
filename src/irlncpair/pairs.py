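"""Rank-pair (0/1) feature construction over DE lncRNAs.

For every unordered pair {A, B} (oriented canonically, A < B by gene id) and
tumour sample s, the feature is 1 iff expression(A) > expression(B) in s, 0
otherwise (ties score 0).  Because the feature depends only on the within-
sample ordering, it is invariant to any strictly monotone per-sample
transform of expression — no cross-sample normalization is needed.  Pairs
whose majority value exceeds 80% of samples carry little discriminative
information and are deleted (boundary kept).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

PAIR_SEP = "|"


def pair_id(a: str, b: str) -> str:
    return f"{a}{PAIR_SEP}{b}"


def split_pair_id(pid: str) -> tuple:
    a, b = pid.split(PAIR_SEP)
    return a, b


def encode_pairs(expr: pd.DataFrame, gene_ids) -> pd.DataFrame:
    """Binary pair matrix (pairs x samples) from a genes-x-samples frame.

    ``expr`` should contain tumour samples only; values may be on any scale
    (only within-sample orderings matter).
    """
    gene_ids = sorted(set(gene_ids))
    missing = [g for g in gene_ids if g not in expr.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing[:5]}")
    if len(gene_ids) < 2:
        raise ValueError("need at least 2 genes to form pairs")
    X = expr.loc[gene_ids].to_numpy()
    m = len(gene_ids)
    iu, ju = np.triu_indices(m, k=1)
    values = (X[iu] > X[ju]).astype(np.int8)
    index = [pair_id(gene_ids[i], gene_ids[j]) for i, j in zip(iu, ju)]
    return pd.DataFrame(values, index=index, columns=expr.columns)


def pair_frequencies(pm: pd.DataFrame) -> pd.Series:
    """One-frequency per pair (fraction of samples scored 1)."""
    return pm.mean(axis=1)


def filter_pairs(pm: pd.DataFrame, low: float = 0.2, high: float = 0.8) -> pd.DataFrame:
    """Constancy filter: keep pairs with low <= freq(1) <= high (boundary kept)."""
    if pm.empty:
        raise ValueError("empty pair matrix")
    if not 0 <= low <= high <= 1:
        raise ValueError("need 0 <= low <= high <= 1")
    f = pair_frequencies(pm)
    return pm.loc[(f >= low) & (f <= high)]


class PairEncoder(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer: samples x genes in, samples x pairs out.

    ``fit`` fixes the canonical pair list and applies the constancy filter on
    the training samples; ``transform`` encodes any sample set over the kept
    pairs (the training-derived pair set is reused unchanged).

    Parameters
    ----------
    genes : list or None
        Genes to pair; default all columns of the fitting frame.
    low, high : float
        Constancy-filter bounds on the one-frequency (inclusive).
    """

    def __init__(self, genes=None, low: float = 0.2, high: float = 0.8):
        self.genes = genes
        self.low = low
        self.high = high

    def fit(self, X: pd.DataFrame, y=None):
        genes = list(self.genes) if self.genes is not None else list(X.columns)
        pm = encode_pairs(X.T, genes)
        self.n_pairs_total_ = len(pm)
        kept = filter_pairs(pm, self.low, self.high)
        self.pairs_ = list(kept.index)
        self.frequencies_ = pair_frequencies(pm)
        self.genes_ = sorted(set(genes))
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "pairs_"):
            raise RuntimeError("PairEncoder is not fitted")
        pm = encode_pairs(X.T, self.genes_)
        return pm.loc[self.pairs_].T

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.pairs_, dtype=object)
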