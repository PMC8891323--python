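"""Synthetic tumour cohorts with planted ground truth.

The generator emulates the statistical structure the pair-signature analysis
assumes: log-normal expression, lncRNA–immune-gene coexpression implanted via
shared latent factors, tumour/normal differential expression, exponential
survival whose hazard depends on the 0/1 ordering of planted lncRNA pairs,
independent uniform censoring calibrated to a target fraction, clinical
covariates associated with risk, planted expression subtypes, and
infiltration / microenvironment-score / drug-IC50 tables with planted
monotone associations.  Every downstream stage of the pipeline is therefore
testable against a known truth without any external download.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

ICI_GENES = ["PDCD1", "CD274", "CTLA4", "LAG3", "HAVCR2", "TIGIT", "IDO1", "PDCD1LG2"]

INFIL_METHODS = ["XCELL", "TIMER", "QUANTISEQ", "MCPCOUNTER", "EPIC",
                 "CIBERSORT-ABS", "CIBERSORT"]
INFIL_CELL_TYPES = ["B cell", "CD4+ T cell", "CD8+ T cell", "Macrophage",
                    "Neutrophil", "Myeloid dendritic cell", "NK cell",
                    "Cancer associated fibroblast"]
# sign of the planted association between infiltration score and risk
_INFIL_SIGNS = {ct: (-1.0 if ct in ("CD4+ T cell", "NK cell") else 1.0)
                for ct in INFIL_CELL_TYPES}


class ConfigurationError(ValueError):
    """Raised when a cohort configuration is internally inconsistent."""


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort.

    Defaults mirror a TCGA-BLCA-like study: 394 tumour and 18 normal samples,
    96 differentially expressed lncRNAs (15 down / 81 up), coexpression target
    r = 0.6 against immune genes, |log2FC| = 3 planted differential shifts,
    four planted prognostic pairs with |beta| = 0.8, roughly 30% censoring,
    and three expression subtypes.
    """

    n_tumour: int = 394
    n_normal: int = 18
    n_lncrna: int = 300
    n_immune_genes: int = 200
    n_other_genes: int = 500
    n_coexpressed_lnc: int = 150
    coexpression_r: float = 0.6
    n_de_lnc_up: int = 81
    n_de_lnc_down: int = 15
    de_log2fc: float = 3.0
    planted_pairs: list | None = None        # [(lnc_a, lnc_b, beta)]; None -> default 4 pairs
    n_planted_pairs: int = 4                  # used when planted_pairs is None
    planted_beta: float = 0.8                 # |beta| used for default pairs
    baseline_hazard: float = 1.0 / 1500.0     # events per day
    censoring_fraction_target: float = 0.30
    n_clusters: int = 3
    cluster_sep: float = 3.0                  # log2-unit mean shift flipping pair orderings
    cluster_log_hr: tuple = ()                # per-cluster log-hazard offsets (default none)
    clinical_assoc: float = 0.8               # log-odds of advanced stage/grade per SD of risk
    infiltration_assoc: float = 0.5           # |rho|-scale association score ~ risk
    drug_assoc: float = 0.6
    n_drugs: int = 30
    estimate_cluster_sep: float = 1.5         # SD-units shift of microenvironment scores per cluster
    seed: int = 0

    def validate(self) -> None:
        counts = dict(n_tumour=self.n_tumour, n_normal=self.n_normal,
                      n_lncrna=self.n_lncrna, n_immune_genes=self.n_immune_genes,
                      n_other_genes=self.n_other_genes, n_clusters=self.n_clusters)
        for name, v in counts.items():
            if v <= 0:
                raise ConfigurationError(f"{name} must be > 0 (got {v})")
        if self.n_de_lnc_up + self.n_de_lnc_down > self.n_lncrna:
            raise ConfigurationError("more DE lncRNAs requested than lncRNAs")
        if self.n_coexpressed_lnc > self.n_lncrna:
            raise ConfigurationError("n_coexpressed_lnc exceeds n_lncrna")
        if not 0 <= self.coexpression_r <= 1:
            raise ConfigurationError("coexpression_r must be in [0, 1]")
        if not 0 <= self.censoring_fraction_target < 1:
            raise ConfigurationError("censoring_fraction_target must be in [0, 1)")
        if self.cluster_log_hr and len(self.cluster_log_hr) != self.n_clusters:
            raise ConfigurationError("cluster_log_hr length must equal n_clusters")


@dataclass
class GroundTruth:
    de_lnc_ids_up: list
    de_lnc_ids_down: list
    coexpressed_lnc_ids: list
    planted_pairs: list                       # [(("A","B"), beta)] canonical orientation
    cluster_labels: dict                      # tumour sample -> cluster int
    true_risk: dict                           # tumour sample -> linear predictor
    censoring_fraction: float = np.nan


@dataclass
class CohortBundle:
    expression: pd.DataFrame                  # genes x samples, linear scale
    condition: pd.Series                      # sample -> {normal, tumour}
    clinical: pd.DataFrame                    # tumour samples
    annotation: pd.DataFrame                  # gene_id, symbol, biotype
    immune_symbols: list
    infiltration: pd.DataFrame                # sample_id, cell_type, method, score
    estimate_scores: pd.DataFrame             # sample_id, StromalScore, ImmuneScore, ESTIMATEScore
    ic50: pd.DataFrame                        # sample_id, drug, ic50
    truth: GroundTruth
    config: CohortConfig


def _lnc_id(i):
    return f"LNC{i:04d}"


def _default_planted_pairs(cfg: CohortConfig):
    """Pair up the first 2*n_planted_pairs coexpressed, up-regulated lncRNAs.

    Members share the same tumour mean so each pair's 0/1 ordering is close to
    balanced and survives the constancy filter; betas alternate in sign.
    """
    need = 2 * cfg.n_planted_pairs
    pool = min(cfg.n_de_lnc_up, cfg.n_coexpressed_lnc)
    if need > pool:
        raise ConfigurationError(
            f"{cfg.n_planted_pairs} planted pairs need {need} coexpressed DE "
            f"lncRNAs; only {pool} available")
    pairs = []
    for i in range(cfg.n_planted_pairs):
        beta = cfg.planted_beta * (1 if i % 2 == 0 else -1)
        pairs.append((_lnc_id(2 * i), _lnc_id(2 * i + 1), beta))
    return pairs


def _canonical_pair(a: str, b: str):
    return (a, b) if a < b else (b, a)


def generate_cohort(config: CohortConfig) -> CohortBundle:
    """Draw a fully labelled synthetic cohort. Reproducible given ``config.seed``."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    lnc_ids = [_lnc_id(i) for i in range(cfg.n_lncrna)]
    imm_ids = [f"IMM{i:04d}" for i in range(cfg.n_immune_genes)]
    oth_ids = [f"OTH{i:04d}" for i in range(cfg.n_other_genes)]
    imm_symbols = (ICI_GENES[: min(len(ICI_GENES), cfg.n_immune_genes)]
                   + [f"IMMS{i}" for i in range(len(ICI_GENES), cfg.n_immune_genes)])

    tum = [f"T{i:03d}" for i in range(cfg.n_tumour)]
    nor = [f"N{i:03d}" for i in range(cfg.n_normal)]
    samples = tum + nor
    n_s, n_t = len(samples), cfg.n_tumour

    # --- role assignment -------------------------------------------------
    coexp = lnc_ids[: cfg.n_coexpressed_lnc]
    # DE genes drawn preferentially from the coexpressed set so they pass the
    # immune-relatedness screen (as the real pipeline requires).
    de_up = lnc_ids[: cfg.n_de_lnc_up] if cfg.n_de_lnc_up <= cfg.n_coexpressed_lnc \
        else coexp + lnc_ids[cfg.n_coexpressed_lnc:cfg.n_de_lnc_up]
    de_down = lnc_ids[cfg.n_de_lnc_up: cfg.n_de_lnc_up + cfg.n_de_lnc_down]

    planted = cfg.planted_pairs if cfg.planted_pairs is not None \
        else (_default_planted_pairs(cfg) if cfg.n_planted_pairs > 0 else [])
    de_set = set(de_up) | set(de_down)
    seen = set()
    for a, b, beta in planted:
        if a == b:
            raise ConfigurationError(f"degenerate pair ({a},{b})")
        if a not in de_set or b not in de_set:
            raise ConfigurationError(f"planted pair members must be DE lncRNAs: ({a},{b})")
        if a in seen or b in seen:
            raise ConfigurationError("planted pairs must have disjoint members")
        seen |= {a, b}

    # --- cluster assignment and pair-flipping mean shifts ----------------
    # Cluster c shifts the members of "its" planted pairs so the expected
    # pair ordering flips between clusters.  Shifts are centred over tumour
    # samples (tumour means, hence log2FC, stay exact) and their variance is
    # folded into the member genes' variance budget below so the planted
    # coexpression correlation stays on target.
    if cfg.n_clusters > 1:
        base = np.repeat(np.arange(cfg.n_clusters), int(np.ceil(n_t / cfg.n_clusters)))[:n_t]
        clusters = rng.permutation(base)
    else:
        clusters = np.zeros(n_t, dtype=int)
    shift = {}                                   # gene -> centred per-tumour shift
    if cfg.n_clusters > 1 and cfg.cluster_sep > 0:
        for p_i, (a, b, _) in enumerate(planted):
            owner = p_i % cfg.n_clusters
            s = np.where(clusters == owner, 1.0, -1.0) * cfg.cluster_sep / 2
            s = s - s.mean()
            shift[a] = s
            shift[b] = -s

    # --- expression on log2 scale ----------------------------------------
    all_ids = lnc_ids + imm_ids + oth_ids
    mu = rng.uniform(3.0, 8.0, size=len(all_ids))
    sd = rng.uniform(0.6, 1.2, size=len(all_ids))
    idx = {g: i for i, g in enumerate(all_ids)}
    # planted pair members share mean/sd so orderings are balanced
    for a, b, _ in planted:
        mu[idx[b]] = mu[idx[a]]
        sd[idx[b]] = sd[idx[a]]

    Z = rng.standard_normal((cfg.n_immune_genes, n_s))      # immune latents
    E = rng.standard_normal((len(all_ids), n_s))            # idiosyncratic noise
    log2x = np.empty((len(all_ids), n_s))
    r = cfg.coexpression_r
    imm_set, coexp_set = set(imm_ids), set(coexp)
    for i, g in enumerate(all_ids):
        v_c = float(np.var(shift[g])) if g in shift else 0.0
        if g in imm_set:
            j = idx[g] - cfg.n_lncrna
            log2x[i] = mu[i] + sd[i] * Z[j]
        elif g in coexp_set:
            j = idx[g] % cfg.n_immune_genes
            if v_c > 0:
                # widen the gene so latent + noise + cluster shift realize the
                # target correlation: alpha/sd_tot = r with sd_tot^2 budgeted
                sd_tot = max(sd[i], 1.02 * np.sqrt(v_c / max(1e-9, 1 - r * r)))
            else:
                sd_tot = sd[i]
            alpha = r * sd_tot
            beta_n = np.sqrt(max(0.0, sd_tot ** 2 - alpha ** 2 - v_c))
            log2x[i] = mu[i] + alpha * Z[j] + beta_n * E[i]
        else:
            log2x[i] = mu[i] + sd[i] * E[i]

    t_cols = np.arange(n_t)
    for g, s in shift.items():
        log2x[idx[g], t_cols] += s

    # differential expression: shift tumour columns
    for g in de_up:
        log2x[idx[g], t_cols] += cfg.de_log2fc
    for g in de_down:
        log2x[idx[g], t_cols] -= cfg.de_log2fc

    expr = pd.DataFrame(np.exp2(log2x), index=all_ids, columns=samples)
    condition = pd.Series(["tumour"] * n_t + ["normal"] * cfg.n_normal,
                          index=samples, name="condition")

    # --- survival ---------------------------------------------------------
    tum_expr = expr[tum]
    lp = np.zeros(n_t)
    canon_pairs = []
    for a, b, beta in planted:
        ca, cb = _canonical_pair(a, b)
        s = (tum_expr.loc[ca].to_numpy() > tum_expr.loc[cb].to_numpy()).astype(float)
        # Flipping orientation maps S -> 1-S (continuous values, no ties), which
        # only shifts the baseline hazard; the canonical beta is the negation.
        beta_c = beta if (ca, cb) == (a, b) else -beta
        lp += beta_c * s
        canon_pairs.append(((ca, cb), beta_c))
    if cfg.cluster_log_hr:
        lp = lp + np.asarray(cfg.cluster_log_hr)[clusters]

    T = rng.exponential(1.0 / (cfg.baseline_hazard * np.exp(lp)))
    if cfg.censoring_fraction_target > 0:
        u = rng.uniform(size=n_t)
        lo, hi = 1.0, float(T.max() * 100 + 1)
        # realized censoring fraction is monotone decreasing in c_max: bisect
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            frac = float(np.mean(mid * u < T))
            if frac > cfg.censoring_fraction_target:
                lo = mid
            else:
                hi = mid
        c_max = 0.5 * (lo + hi)
        C = c_max * u
        os_days = np.minimum(T, C)
        event = (T <= C).astype(int)
    else:
        os_days, event = T, np.ones(n_t, dtype=int)
    os_days = np.maximum(os_days, 0.5)        # keep times strictly positive

    # --- clinical covariates ----------------------------------------------
    zrisk = (lp - lp.mean()) / (lp.std() if lp.std() > 0 else 1.0)
    age = np.clip(np.round(rng.normal(68, 10, n_t)), 34, 90)
    sex = np.where(rng.uniform(size=n_t) < 0.74, "male", "female")

    def _logistic(p_base, slope):
        z = np.log(p_base / (1 - p_base)) + slope * zrisk
        return rng.uniform(size=n_t) < 1 / (1 + np.exp(-z))

    grade = np.where(_logistic(0.6, cfg.clinical_assoc), "High", "Low")
    stage_latent = cfg.clinical_assoc * zrisk + rng.logistic(size=n_t)
    stage_cut = np.quantile(stage_latent, [0.2, 0.5, 0.8])
    stage_num = 1 + np.searchsorted(stage_cut, stage_latent)
    stage = np.array(["I", "II", "III", "IV"])[stage_num - 1]
    t_stage = np.array(["T1", "T2", "T3", "T4"])[
        np.clip(stage_num - 1 + rng.integers(-1, 1, n_t), 0, 3)]
    n_stage = np.where(_logistic(0.25, 0.5 * cfg.clinical_assoc), "N1", "N0")
    m_stage = np.where(_logistic(0.1, 0.5 * cfg.clinical_assoc), "M1", "M0")
    clinical = pd.DataFrame({
        "sample_id": tum, "os_days": os_days, "os_event": event,
        "age": age.astype(int), "sex": sex, "grade": grade, "stage": stage,
        "T": t_stage, "N": n_stage, "M": m_stage,
    })

    # --- infiltration / ESTIMATE / IC50 -----------------------------------
    rows = []
    a = cfg.infiltration_assoc
    for method in INFIL_METHODS:
        for ct in INFIL_CELL_TYPES:
            noise = rng.standard_normal(n_t)
            score = _INFIL_SIGNS[ct] * a * zrisk + np.sqrt(max(0.0, 1 - a * a)) * noise
            for s_id, v in zip(tum, score):
                rows.append((s_id, ct, method, float(v)))
    infiltration = pd.DataFrame(rows, columns=["sample_id", "cell_type", "method", "score"])

    shift = (clusters - (cfg.n_clusters - 1) / 2) * cfg.estimate_cluster_sep
    stromal = rng.normal(0, 1, n_t) + shift
    immune_sc = rng.normal(0, 1, n_t) + shift
    estimate = pd.DataFrame({
        "sample_id": tum,
        "StromalScore": 1000 * stromal,
        "ImmuneScore": 1000 * immune_sc,
        "ESTIMATEScore": 1000 * (stromal + immune_sc),
    })

    drugs = [f"Drug{i:02d}" for i in range(cfg.n_drugs)]
    rows = []
    for k, drug in enumerate(drugs):
        if k < cfg.n_drugs // 2:
            sign = -1.0 if k % 2 == 0 else 1.0     # half the drugs associated
            mu_d = sign * cfg.drug_assoc * zrisk
        else:
            mu_d = np.zeros(n_t)
        vals = mu_d + rng.standard_normal(n_t)
        for s_id, v in zip(tum, vals):
            rows.append((s_id, drug, float(v)))
    ic50 = pd.DataFrame(rows, columns=["sample_id", "drug", "ic50"])

    annotation = pd.DataFrame({
        "gene_id": all_ids,
        "symbol": ([f"LNCS{i}" for i in range(cfg.n_lncrna)] + imm_symbols
                   + [f"OTHS{i}" for i in range(cfg.n_other_genes)]),
        "biotype": (["lncRNA"] * cfg.n_lncrna
                    + ["protein_coding"] * (cfg.n_immune_genes + cfg.n_other_genes)),
    })

    truth = GroundTruth(
        de_lnc_ids_up=list(de_up), de_lnc_ids_down=list(de_down),
        coexpressed_lnc_ids=list(coexp),
        planted_pairs=canon_pairs,
        cluster_labels={s: int(c) for s, c in zip(tum, clusters)},
        true_risk={s: float(v) for s, v in zip(tum, lp)},
        censoring_fraction=float(1 - event.mean()),
    )
    return CohortBundle(expression=expr, condition=condition, clinical=clinical,
                        annotation=annotation, immune_symbols=imm_symbols,
                        infiltration=infiltration, estimate_scores=estimate,
                        ic50=ic50, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------

def write_fixture(bundle: CohortBundle, directory) -> dict:
    """Write the bundle as the on-disk TSV/text interchange formats.

    Returns a manifest mapping logical names to paths; empty optional tables
    are omitted and noted in ``manifest.json``.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {}

    expr = bundle.expression.copy()
    expr.index.name = "gene_id"
    expr.to_csv(d / "expression.tsv", sep="\t")
    paths["expression"] = "expression.tsv"

    cond = bundle.condition.rename_axis("sample_id").reset_index()
    cond.to_csv(d / "samples.tsv", sep="\t", index=False)
    paths["samples"] = "samples.tsv"

    bundle.clinical.to_csv(d / "clinical.tsv", sep="\t", index=False, na_rep="NA")
    paths["clinical"] = "clinical.tsv"

    bundle.annotation.to_csv(d / "annotation.tsv", sep="\t", index=False)
    paths["annotation"] = "annotation.tsv"

    with open(d / "immune_genes.txt", "w") as fh:
        fh.write("# immune-related gene symbols\n")
        fh.writelines(s + "\n" for s in bundle.immune_symbols)
    paths["immune_genes"] = "immune_genes.txt"

    absent = []
    for name, df, fn in [("infiltration", bundle.infiltration, "infiltration.tsv"),
                         ("estimate", bundle.estimate_scores, "estimate.tsv"),
                         ("ic50", bundle.ic50, "ic50.tsv")]:
        if df is None or len(df) == 0:
            absent.append(name)
        else:
            df.to_csv(d / fn, sep="\t", index=False)
            paths[name] = fn

    gt_rows = []
    for g in bundle.truth.de_lnc_ids_up:
        gt_rows.append(("de_up", g, ""))
    for g in bundle.truth.de_lnc_ids_down:
        gt_rows.append(("de_down", g, ""))
    for g in bundle.truth.coexpressed_lnc_ids:
        gt_rows.append(("coexpressed", g, ""))
    for (a, b), beta in bundle.truth.planted_pairs:
        gt_rows.append(("planted_pair", f"{a}|{b}", repr(beta)))
    for s, c in bundle.truth.cluster_labels.items():
        gt_rows.append(("cluster", s, str(c)))
    for s, v in bundle.truth.true_risk.items():
        gt_rows.append(("true_risk", s, repr(v)))
    pd.DataFrame(gt_rows, columns=["item", "id", "value"]).to_csv(
        d / "ground_truth.tsv", sep="\t", index=False)
    paths["ground_truth"] = "ground_truth.tsv"

    cfg = dataclasses.asdict(bundle.config)
    cfg["cluster_log_hr"] = list(cfg["cluster_log_hr"])
    with open(d / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    paths["config"] = "config.yaml"

    with open(d / "manifest.json", "w") as fh:
        json.dump({"files": paths, "absent": absent}, fh, indent=2)
    return {k: str(d / v) for k, v in paths.items()}
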