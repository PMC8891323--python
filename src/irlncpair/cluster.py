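"""Consensus clustering of tumour samples on the signature's pair features.

Monti-style resampling consensus: repeatedly subsample samples, cluster each
subsample by average-linkage hierarchical agglomeration on Hamming distance
of the binary pair features, and record how often each sample pair lands in
the same cluster.  The consensus matrix at each k feeds cluster-number
selection (consensus-CDF delta-area by default; PAC also reported) and the
final labels come from hierarchically clustering 1 − consensus.  PCA and
survival / microenvironment comparisons validate the clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA

from .stats import bh_fdr, kruskal_test, logrank_test, ranksum_test

log = logging.getLogger("irlncpair")


@dataclass
class ConsensusResult:
    k_range: list
    consensus: dict                  # k -> samples x samples DataFrame in [0,1]
    labels: dict                     # k -> pd.Series of int labels (1..k)
    area: dict                       # k -> area under consensus CDF
    delta_area: dict                 # k -> relative area increase
    pac: dict                        # k -> proportion of ambiguous clustering
    chosen_k: int = 0
    final_labels: pd.Series = field(default=None)


def _cdf_area(consensus_values: np.ndarray) -> float:
    # area under the empirical CDF on [0,1] equals 1 - mean(values)
    return float(1.0 - consensus_values.mean())


def consensus_cluster(pm: pd.DataFrame, k_range=range(2, 7), reps: int = 100,
                      item_fraction: float = 0.8, seed: int = 0,
                      k: int | None = None, linkage_method: str = "average",
                      pac_bounds=(0.1, 0.9)) -> ConsensusResult:
    """Monti resampling consensus over binary pair features (pairs x samples).

    ``k`` fixes the cluster number (the replication profile uses k=3);
    otherwise the delta-area rule chooses it over ``k_range``.
    """
    if pm.shape[1] < 20:
        raise ValueError("need at least 20 samples")
    if pm.shape[0] < 2:
        raise ValueError("need at least 2 features")
    k_range = [int(x) for x in k_range]
    rng = np.random.default_rng(seed)
    data = pm.T.to_numpy(dtype=float)       # samples x features
    n = data.shape[0]
    m = max(2, int(round(item_fraction * n)))

    co_sample = np.zeros((n, n))
    co_cluster = {kk: np.zeros((n, n)) for kk in k_range}
    eye = np.eye(n)
    for _ in range(reps):
        idx = rng.choice(n, size=m, replace=False)
        co_sample[np.ix_(idx, idx)] += 1
        D = pdist(data[idx], metric="hamming")
        Z = linkage(D, method=linkage_method)
        for kk in k_range:
            lab = fcluster(Z, kk, criterion="maxclust")
            for c in np.unique(lab):
                mem = idx[lab == c]
                co_cluster[kk][np.ix_(mem, mem)] += 1
    off = ~eye.astype(bool)
    if (co_sample[off] == 0).any():
        raise RuntimeError("some sample pairs were never co-subsampled; increase reps")

    consensus, labels, area, pac = {}, {}, {}, {}
    for kk in k_range:
        M = np.where(co_sample > 0, co_cluster[kk] / np.maximum(co_sample, 1), 0.0)
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2.0
        consensus[kk] = pd.DataFrame(M, index=pm.columns, columns=pm.columns)
        Z = linkage(squareform(1.0 - M, checks=False), method=linkage_method)
        labels[kk] = pd.Series(fcluster(Z, kk, criterion="maxclust"),
                               index=pm.columns, name="cluster")
        vals = M[np.triu_indices(n, k=1)]
        area[kk] = _cdf_area(vals)
        lo, hi = pac_bounds
        pac[kk] = float(np.mean((vals > lo) & (vals < hi)))

    delta = {}
    ks = sorted(k_range)
    for i, kk in enumerate(ks):
        if i == 0:
            delta[kk] = area[kk]
        else:
            prev = area[ks[i - 1]]
            delta[kk] = (area[kk] - prev) / prev if prev > 0 else 0.0
    chosen = int(k) if k is not None else max(delta, key=delta.get)
    if k is not None and chosen not in labels:
        raise ValueError(f"k={k} outside k_range")
    return ConsensusResult(k_range=ks, consensus=consensus, labels=labels,
                           area=area, delta_area=delta, pac=pac,
                           chosen_k=chosen, final_labels=labels[chosen])


class ConsensusCluster(BaseEstimator, ClusterMixin):
    """Sklearn-style wrapper: ``fit(X)`` with samples x pair-features (0/1).

    Fitted attributes: ``labels_`` (0-based), ``chosen_k_``, ``result_``.
    """

    def __init__(self, k=None, k_range=(2, 3, 4, 5, 6), reps: int = 100,
                 item_fraction: float = 0.8, seed: int = 0):
        self.k = k
        self.k_range = k_range
        self.reps = reps
        self.item_fraction = item_fraction
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None):
        res = consensus_cluster(X.T, k_range=self.k_range, reps=self.reps,
                                item_fraction=self.item_fraction,
                                seed=self.seed, k=self.k)
        self.result_ = res
        self.chosen_k_ = res.chosen_k
        self.labels_ = res.final_labels.to_numpy() - 1
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def pca_embed(pm: pd.DataFrame, labels: pd.Series | None = None) -> tuple:
    """Centered 2-D PCA of samples on pair features.

    Returns (coords DataFrame with PC1/PC2 and optional cluster column,
    explained-variance ratios).  Zero-variance features are dropped.
    """
    X = pm.T
    keep = X.std(axis=0) > 0
    if (~keep).any():
        log.warning("pca_embed: dropping %d zero-variance feature(s)", int((~keep).sum()))
    X = X.loc[:, keep]
    if X.shape[1] < 2:
        raise ValueError("need at least 2 non-constant features")
    p = PCA(n_components=2)
    coords = p.fit_transform(X.to_numpy(dtype=float))
    out = pd.DataFrame(coords, index=X.index, columns=["PC1", "PC2"])
    if labels is not None:
        out["cluster"] = labels.loc[out.index].to_numpy()
    return out, p.explained_variance_ratio_


def cluster_comparisons(labels: pd.Series, clinical: pd.DataFrame,
                        estimate_scores: pd.DataFrame | None = None,
                        ici_expr: pd.DataFrame | None = None,
                        min_cluster_size: int = 5) -> dict:
    """Survival, microenvironment-score and checkpoint-gene tests across clusters.

    Returns a dict with ``survival`` (log-rank), ``scores`` (Kruskal–Wallis per
    score column with pairwise rank-sum follow-ups), and ``genes``.
    """
    sizes = labels.value_counts()
    good = sizes.index[sizes >= min_cluster_size]
    if len(good) < 2:
        raise ValueError("need at least 2 clusters of sufficient size")
    if len(good) < len(sizes):
        log.warning("cluster_comparisons: skipping %d degenerate cluster(s)",
                    len(sizes) - len(good))
    lab = labels[labels.isin(good)]
    out = {}

    clin = clinical.set_index("sample_id")
    common = lab.index.intersection(clin.index)
    chi2, df, p = logrank_test(lab.loc[common].to_numpy(),
                               clin.loc[common, "os_days"].astype(float),
                               clin.loc[common, "os_event"].astype(int))
    out["survival"] = {"chi2": chi2, "df": df, "p": p}

    if estimate_scores is not None and len(estimate_scores):
        est = estimate_scores.set_index("sample_id")
        rows, pair_rows = [], []
        for col in [c for c in est.columns if c.endswith("Score")]:
            groups = [est.loc[lab.index[lab == g].intersection(est.index), col]
                      for g in good]
            h, p = kruskal_test(groups)
            rows.append((col, h, p))
            for (g1, v1), (g2, v2) in combinations(zip(good, groups), 2):
                _, pp = ranksum_test(v1, v2)
                pair_rows.append((col, g1, g2, pp))
        out["scores"] = pd.DataFrame(rows, columns=["score", "H", "p"])
        out["scores_pairwise"] = pd.DataFrame(
            pair_rows, columns=["score", "cluster_a", "cluster_b", "p"])

    if ici_expr is not None and len(ici_expr):
        rows = []
        X = np.log2(ici_expr + 1.0)
        for g, s in X.iterrows():
            groups = [s[lab.index[lab == c].intersection(s.index)] for c in good]
            if any(len(v) == 0 for v in groups):
                continue
            h, p = kruskal_test(groups)
            rows.append((g, h, p))
        genes = pd.DataFrame(rows, columns=["gene", "H", "p"])
        genes["q"] = bh_fdr(genes["p"]) if len(genes) else []
        out["genes"] = genes
    return out
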