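"""End-to-end orchestration of the pair-signature analysis.

``run_all`` executes screen -> pairs -> split -> build -> cutoff -> evaluate
-> cluster on one configuration and writes every stage's tables plus a run
manifest (config echo, derived stage seeds, per-stage counts).  Stage seeds
are derived deterministically from the master seed as
``(master_seed * 1_000_003 + stage_index) mod 2**31`` so a run replays
exactly.  Individual stage functions back the CLI subcommands.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import evaluate as ev
from . import io as cio
from . import roc as tdr
from . import screen as sc
from . import signature as sig
from .pairs import encode_pairs, filter_pairs, pair_frequencies
from .stats import logrank_test

log = logging.getLogger("irlncpair")

STAGES = ["screen", "pairs", "train", "cutoff", "evaluate", "cluster"]


def derive_seed(master_seed: int, stage_index: int) -> int:
    return (master_seed * 1_000_003 + stage_index) % (2 ** 31)


@dataclass
class RunConfig:
    """All inputs and thresholds of a run (YAML-serializable)."""

    expression: str = ""
    samples: str = ""
    clinical: str = ""
    annotation: str = ""
    immune_genes: str = ""
    infiltration: str | None = None
    estimate: str | None = None
    ic50: str | None = None

    r_threshold: float = 0.4
    corr_p_threshold: float = 0.001
    lfc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    pair_low: float = 0.2
    pair_high: float = 0.8
    split_ratio: float = 0.5
    univariate_p: float = 0.05
    lasso_folds: int = 10
    horizons: tuple = tdr.DEFAULT_HORIZONS
    cutoff_method: str = "aic"
    k_range: tuple = (2, 3, 4, 5, 6)
    fixed_k: int | None = 3          # replication profile: three clusters
    consensus_reps: int = 100
    item_fraction: float = 0.8
    ici_genes: tuple = tuple(ev.DEFAULT_ICI_GENES)
    seed: int = 0

    def validate(self):
        if not (0 < self.split_ratio < 1):
            raise ValueError("split_ratio must be in (0,1)")
        if not (0 <= self.pair_low <= self.pair_high <= 1):
            raise ValueError("pair bounds must satisfy 0<=low<=high<=1")
        sc.ScreenConfig(self.r_threshold, self.corr_p_threshold,
                        self.lfc_threshold, self.fdr_threshold).validate()
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path):
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _write(df: pd.DataFrame, path: Path, **kw):
    df.to_csv(path, sep="\t", **kw)


def run_all(config: RunConfig, out_dir) -> dict:
    """Run the whole analysis; returns the manifest dict."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": dataclasses.asdict(config), "counts": {}, "seeds": {},
                "skipped": []}
    for k, v in manifest["config"].items():
        if isinstance(v, tuple):
            manifest["config"][k] = list(v)

    def fail(stage, exc):
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # ---- inputs ----------------------------------------------------------
    try:
        expr = cio.read_expression(config.expression, config.samples or None)
        clinical = cio.read_clinical(config.clinical)
        annotation = cio.read_annotation(config.annotation)
        immune = cio.read_gene_list(config.immune_genes)
        infiltration = cio.read_infiltration(config.infiltration) if config.infiltration else None
        estimate = cio.read_estimate(config.estimate) if config.estimate else None
        ic50 = cio.read_ic50(config.ic50) if config.ic50 else None
    except Exception as exc:
        fail("load", exc)
    manifest["counts"]["n_tumour"] = len(expr.tumour_samples)
    manifest["counts"]["n_normal"] = len(expr.normal_samples)
    manifest["counts"]["clinical_dropped_zero_followup"] = \
        clinical.attrs.get("n_dropped_zero_followup", 0)

    screen_cfg = sc.ScreenConfig(config.r_threshold, config.corr_p_threshold,
                                 config.lfc_threshold, config.fdr_threshold)

    # ---- screen ----------------------------------------------------------
    try:
        lnc, imm, _ = cio.classify_genes(annotation, immune)
        ir = sc.coexpression_filter(expr, sorted(lnc), sorted(imm), screen_cfg)
        _write(ir, out / "irlncrna.tsv", index=False)
        de = sc.differential_expression(expr, list(ir["lncrna"]), screen_cfg)
        _write(de, out / "de_irlncrna.tsv", index=False)
        de_ids = sc.de_gene_ids(de)
    except Exception as exc:
        fail("screen", exc)
    manifest["counts"].update(
        n_lncrna=len(lnc), n_immune_mrna=len(imm), n_irlncrna=len(ir),
        n_de_irlncrna=len(de_ids),
        n_de_up=int((de["direction"] == "up").sum()),
        n_de_down=int((de["direction"] == "down").sum()))

    # ---- pairs -----------------------------------------------------------
    try:
        if len(de_ids) < 2:
            raise RuntimeError("fewer than 2 DE lncRNAs; cannot form pairs")
        tum_expr = expr.values[expr.tumour_samples]
        pm_all = encode_pairs(tum_expr, de_ids)
        freq = pair_frequencies(pm_all)
        pm = filter_pairs(pm_all, config.pair_low, config.pair_high)
        freq_tab = pd.DataFrame({"pair": freq.index, "one_frequency": freq.values,
                                 "kept": freq.index.isin(pm.index)})
        _write(pm, out / "pairs.tsv", index_label="pair")
        _write(freq_tab, out / "pair_freq.tsv", index=False)
    except Exception as exc:
        fail("pairs", exc)
    manifest["counts"]["pairs_total"] = len(pm_all)
    manifest["counts"]["pairs_after_filter"] = len(pm)

    # ---- train -----------------------------------------------------------
    try:
        ids, clin = cio.intersect_samples(expr, clinical)
        pm = pm[ids]
        split_seed = derive_seed(config.seed, 2)
        train_ids, test_ids = sig.split_cohort(clin, ratio=config.split_ratio,
                                               seed=split_seed)
        surv = clin.set_index("sample_id")
        t_tr = surv.loc[train_ids, "os_days"].astype(float).to_numpy()
        e_tr = surv.loc[train_ids, "os_event"].astype(int).to_numpy()
        signature = sig.build_signature(
            pm[train_ids], t_tr, e_tr, univariate_p=config.univariate_p,
            folds=config.lasso_folds, seed=derive_seed(config.seed, 3))
        scores = sig.risk_scores(signature, pm)
        with open(out / "signature.json", "w") as fh:
            json.dump({**signature.to_dict(), "seed": config.seed,
                       "thresholds": {"univariate_p": config.univariate_p,
                                      "folds": config.lasso_folds}},
                      fh, indent=2, default=float)
        score_tab = pd.DataFrame({
            "sample_id": scores.index, "risk_score": scores.values,
            "set": ["train" if s in set(train_ids) else "test" for s in scores.index]})
        _write(score_tab, out / "risk_scores.tsv", index=False)
    except Exception as exc:
        fail("train", exc)
    manifest["seeds"] = {"split": derive_seed(config.seed, 2),
                         "lasso": derive_seed(config.seed, 3),
                         "cluster": derive_seed(config.seed, 6)}
    manifest["counts"].update(n_train=len(train_ids), n_test=len(test_ids),
                              **{k: v for k, v in signature.trace.items()
                                 if isinstance(v, (int, np.integer))})

    # ---- cutoff ----------------------------------------------------------
    try:
        strat = tdr.RiskStratifier(horizon=config.horizons[0],
                                   method=config.cutoff_method)
        strat.fit(scores.loc[train_ids].to_numpy(), t_tr, e_tr)
        groups = strat.predict(scores)
        auc_rows = []
        for name, id_set in [("train", train_ids), ("test", test_ids),
                             ("entire", ids)]:
            tt = surv.loc[id_set, "os_days"].astype(float).to_numpy()
            ee = surv.loc[id_set, "os_event"].astype(int).to_numpy()
            for h in config.horizons:
                try:
                    roc = tdr.td_roc(scores.loc[id_set].to_numpy(), tt, ee, h)
                except ValueError as exc:
                    log.warning("td_roc %s @%sd skipped: %s", name, h, exc)
                    continue
                auc_rows.append((name, h, roc.auc))
                if name == "train":
                    _write(roc.table(), out / f"roc_{int(h)}.tsv", index=False)
        _write(pd.DataFrame(auc_rows, columns=["set", "horizon_days", "auc"]),
               out / "auc.tsv", index=False)
        cut_tab = strat.candidates_.copy()
        cut_tab["chosen"] = cut_tab["cutoff"] == strat.cutoff_
        cut_tab["method"] = config.cutoff_method
        _write(cut_tab, out / "cutoff.tsv", index=False)
        km_rows = []
        for name, id_set in [("train", train_ids), ("test", test_ids), ("entire", ids)]:
            g = groups.loc[id_set]
            if g.nunique() < 2:
                continue
            chi2, dof, p = logrank_test(g.to_numpy(),
                                        surv.loc[id_set, "os_days"].astype(float),
                                        surv.loc[id_set, "os_event"].astype(int))
            km_rows.append((name, chi2, dof, p))
        _write(pd.DataFrame(km_rows, columns=["set", "chi2", "df", "p"]),
               out / "km_logrank.tsv", index=False)
    except Exception as exc:
        fail("cutoff", exc)
    manifest["counts"]["cutoff"] = float(strat.cutoff_)
    manifest["counts"]["n_high_risk"] = int((groups == "high").sum())

    # ---- evaluate --------------------------------------------------------
    try:
        _write(ev.clinical_cox(scores.loc[ids], clin, mode="uni"),
               out / "hazard_uni.tsv", index=False)
        _write(ev.clinical_cox(scores.loc[ids], clin, mode="multi"),
               out / "hazard_multi.tsv", index=False)
        _write(ev.risk_group_associations(groups.loc[ids], clin),
               out / "assoc_clinical.tsv", index=False)
        _write(ev.roc_vs_clinical(scores.loc[ids], clin, horizon=config.horizons[0]),
               out / "roc_vs_clinical.tsv", index=False)
        if infiltration is not None:
            _write(ev.infiltration_correlation(scores.loc[ids], infiltration),
                   out / "lollipop.tsv", index=False)
        else:
            manifest["skipped"].append("infiltration")
        ici = ev.group_expression_tests(expr, list(config.ici_genes),
                                        groups.loc[ids], annotation=annotation)
        _write(ici, out / "ici_genes.tsv", index=False)
        if ic50 is not None:
            drug = ev.group_ic50_tests(ic50, groups.loc[ids])
            _write(drug, out / "drug_ic50.tsv", index=False)
            manifest["counts"]["n_drugs_significant"] = int(drug["significant"].sum())
        else:
            manifest["skipped"].append("ic50")
    except Exception as exc:
        fail("evaluate", exc)

    # ---- cluster ---------------------------------------------------------
    try:
        cluster_pairs = list(signature.pairs)
        if len(cluster_pairs) < 2 and signature.lasso_pairs:
            # fall back to the Lasso survivors so subtyping stays feasible
            log.warning("final signature has %d pair(s); clustering on the %d "
                        "lasso survivors instead", len(cluster_pairs),
                        len(signature.lasso_pairs))
            cluster_pairs = sorted(set(cluster_pairs) | set(signature.lasso_pairs))
            manifest["skipped"].append("cluster_on_final_pairs")
        pm_sig = pm.loc[cluster_pairs]
        res = cl.consensus_cluster(pm_sig, k_range=config.k_range,
                                   reps=config.consensus_reps,
                                   item_fraction=config.item_fraction,
                                   seed=derive_seed(config.seed, 6),
                                   k=config.fixed_k)
        _write(pd.DataFrame({"sample_id": res.final_labels.index,
                             "cluster": res.final_labels.values}),
               out / "clusters.tsv", index=False)
        for kk, M in res.consensus.items():
            _write(M.round(4), out / f"consensus_k{kk}.tsv", index_label="sample_id")
        coords, evr = cl.pca_embed(pm_sig, res.final_labels)
        _write(coords, out / "pca.tsv", index_label="sample_id")
        ici_ids = [g for g in annotation.loc[annotation["symbol"].isin(config.ici_genes),
                                             "gene_id"]
                   if g in expr.values.index]
        comp = cl.cluster_comparisons(
            res.final_labels, clin, estimate_scores=estimate,
            ici_expr=expr.values.loc[ici_ids, ids] if ici_ids else None)
        stats_rows = [("survival_logrank", comp["survival"]["chi2"],
                       comp["survival"]["p"])]
        if "scores" in comp:
            stats_rows += [(f"kruskal_{r.score}", r.H, r.p)
                           for r in comp["scores"].itertuples()]
        _write(pd.DataFrame(stats_rows, columns=["test", "statistic", "p"]),
               out / "cluster_stats.tsv", index=False)
        if estimate is None:
            manifest["skipped"].append("estimate")
    except Exception as exc:
        fail("cluster", exc)
    manifest["counts"]["chosen_k"] = res.chosen_k
    manifest["counts"]["delta_area"] = {str(k): round(v, 4)
                                        for k, v in res.delta_area.items()}
    manifest["counts"]["pca_variance_explained"] = [round(float(v), 4) for v in evr]

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def report(out_dir) -> str:
    """Human-readable summary collating a run directory's tables."""
    out = Path(out_dir)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    if "failed_stage" in manifest:
        return f"run FAILED at stage {manifest['failed_stage']}: {manifest['error']}"
    with open(out / "signature.json") as fh:
        s = json.load(fh)
    lines = ["pair-signature analysis summary", "=" * 32, ""]
    c = manifest["counts"]
    lines.append(f"cohort: {c['n_tumour']} tumour / {c['n_normal']} normal samples")
    lines.append(f"immune-related lncRNAs: {c['n_irlncrna']}; "
                 f"DE: {c['n_de_irlncrna']} ({c['n_de_up']} up / {c['n_de_down']} down)")
    lines.append(f"pairs: {c['pairs_total']} total, {c['pairs_after_filter']} after "
                 f"constancy filter")
    lines.append(f"selection: {c.get('k1_univariate', '?')} univariate -> "
                 f"{c.get('k2_lasso', '?')} lasso -> {c.get('k_final', '?')} final")
    lines.append("")
    lines.append("final signature (pair, beta):")
    for p, b in s["coef"].items():
        lines.append(f"  {p:25s} {b:+.4f}")
    auc = pd.read_csv(out / "auc.tsv", sep="\t")
    lines.append("")
    for r in auc.itertuples():
        lines.append(f"AUC {r.set:7s} @{int(r.horizon_days):5d}d: {r.auc:.3f}")
    km = pd.read_csv(out / "km_logrank.tsv", sep="\t")
    for r in km.itertuples():
        lines.append(f"log-rank {r.set:7s}: chi2={r.chi2:.2f}, p={r.p:.3g}")
    lines.append(f"\ncutoff: {c['cutoff']:.4f}; high-risk n={c['n_high_risk']}")
    lines.append(f"clusters: k={c['chosen_k']}")
    return "\n".join(lines)
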