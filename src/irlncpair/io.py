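"""Readers/writers and validation for the tabular interchange formats.

On-disk conventions: expression is a linear-scale TSV with a ``gene_id`` first
column and sample-id columns, accompanied by a ``sample_id<TAB>condition``
table; the clinical table carries overall-survival time in days and a 0/1
event flag plus covariates (``NA`` for missing); gene lists are one symbol per
line with ``#`` comments; annotation, infiltration and IC50 tables are plain
TSV.  Clinical rows with non-positive follow-up are dropped (and counted) on
read.  log2(x+1) is applied internally wherever a log scale is required.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger("irlncpair")

CLINICAL_COLUMNS = ["sample_id", "os_days", "os_event", "age", "sex",
                    "grade", "stage", "T", "N", "M"]


class ValidationError(ValueError):
    """Malformed or inconsistent input table."""


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame          # genes x samples, linear scale, >= 0
    condition: pd.Series          # sample -> {"normal", "tumour"}

    @property
    def tumour_samples(self):
        return list(self.condition.index[self.condition == "tumour"])

    @property
    def normal_samples(self):
        return list(self.condition.index[self.condition == "normal"])

    def log2(self) -> pd.DataFrame:
        return np.log2(self.values + 1.0)


def log2p1(df: pd.DataFrame) -> pd.DataFrame:
    """The package's internal log transform: log2(x + 1)."""
    return np.log2(df + 1.0)


def read_expression(path, samples_path=None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise ValidationError(f"{path}: first column must be 'gene_id', got {df.columns[0]!r}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"{path}: duplicate gene id(s): {sorted(set(dup))[:5]}")
    df = df.set_index("gene_id")
    if df.columns.duplicated().any():
        raise ValidationError(f"{path}: duplicate sample columns")
    vals = df.to_numpy()
    if not np.isfinite(vals).all():
        raise ValidationError(f"{path}: non-finite expression values")
    if (vals < 0).any():
        g, s = np.argwhere(vals < 0)[0]
        raise ValidationError(f"{path}: negative expression at gene {df.index[g]}, "
                              f"sample {df.columns[s]}")
    if samples_path is None:
        samples_path = str(path).replace("expression.tsv", "samples.tsv")
    cond = pd.read_csv(samples_path, sep="\t")
    if list(cond.columns[:2]) != ["sample_id", "condition"]:
        raise ValidationError(f"{samples_path}: expected columns sample_id, condition")
    cond = cond.set_index("sample_id")["condition"]
    missing = [s for s in df.columns if s not in cond.index]
    if missing:
        raise ValidationError(f"{samples_path}: no condition for sample(s) {missing[:5]}")
    bad = set(cond.unique()) - {"normal", "tumour"}
    if bad:
        raise ValidationError(f"{samples_path}: unknown condition(s) {sorted(bad)}")
    return ExpressionMatrix(values=df, condition=cond.loc[df.columns])


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in ("sample_id", "os_days", "os_event") if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids")
    if df["os_days"].isna().any() or df["os_event"].isna().any():
        raise ValidationError(f"{path}: os_days/os_event must not be missing")
    if not df["os_event"].isin([0, 1]).all():
        bad = df.loc[~df["os_event"].isin([0, 1])].index[0]
        raise ValidationError(f"{path}: non-binary os_event at row {bad}")
    n0 = len(df)
    df = df[df["os_days"] > 0].reset_index(drop=True)
    dropped = n0 - len(df)
    if dropped:
        log.info("read_clinical: dropped %d sample(s) with non-positive follow-up", dropped)
    df.attrs["n_dropped_zero_followup"] = dropped
    return df


def read_gene_list(path) -> list:
    symbols = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                symbols.append(line)
    return symbols


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = ["gene_id", "symbol", "biotype"]
    if [c for c in need if c not in df.columns]:
        raise ValidationError(f"{path}: expected columns {need}")
    if df["gene_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate gene ids")
    return df[need]


def read_infiltration(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = ["sample_id", "cell_type", "method", "score"]
    if [c for c in need if c not in df.columns]:
        raise ValidationError(f"{path}: expected columns {need}")
    if df.duplicated(["sample_id", "cell_type", "method"]).any():
        raise ValidationError(f"{path}: duplicate (sample, cell_type, method) rows")
    return df[need]


def read_estimate(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: expected a sample_id column")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids")
    return df


def read_ic50(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = ["sample_id", "drug", "ic50"]
    if [c for c in need if c not in df.columns]:
        raise ValidationError(f"{path}: expected columns {need}")
    if df.duplicated(["sample_id", "drug"]).any():
        raise ValidationError(f"{path}: duplicate (sample, drug) rows")
    return df[need]


def classify_genes(annotation: pd.DataFrame, immune_symbols) -> tuple:
    """Partition gene ids into (lncRNA, immune mRNA, other).

    Biotype takes precedence: a gene annotated ``lncRNA`` is classified as a
    lncRNA even if its symbol appears in the immune list.  Immune mRNAs are
    protein-coding genes whose symbol is in the list.  The three sets are
    disjoint and exhaustive over the annotation.
    """
    immune_symbols = set(immune_symbols)
    if not immune_symbols:
        raise ValidationError("empty immune gene list")
    if annotation.empty:
        raise ValidationError("empty annotation")
    lnc = set(annotation.loc[annotation["biotype"] == "lncRNA", "gene_id"])
    coding = annotation[annotation["biotype"] != "lncRNA"]
    imm = set(coding.loc[(coding["biotype"] == "protein_coding")
                         & coding["symbol"].isin(immune_symbols), "gene_id"])
    other = set(annotation["gene_id"]) - lnc - imm
    unmatched = immune_symbols - set(annotation["symbol"])
    if unmatched:
        log.warning("classify_genes: %d immune symbol(s) absent from annotation",
                    len(unmatched))
    return lnc, imm, other


def intersect_samples(expr: ExpressionMatrix, clinical: pd.DataFrame) -> tuple:
    """Inner-join tumour expression samples with clinical rows; log the rest."""
    tum = set(expr.tumour_samples)
    clin_ids = set(clinical["sample_id"])
    common = sorted(tum & clin_ids)
    lost_expr, lost_clin = sorted(tum - clin_ids), sorted(clin_ids - tum)
    if lost_expr or lost_clin:
        log.info("sample intersection: %d tumour samples without clinical data, "
                 "%d clinical rows without expression", len(lost_expr), len(lost_clin))
    clin = clinical.set_index("sample_id").loc[common].reset_index()
    return common, clin
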