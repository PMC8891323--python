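# irlncpair

Rank-pair immune-related lncRNA prognostic signatures for tumour cohorts.

Most expression-based prognostic signatures depend on the measured level of
each gene, so they break down across platforms and batches unless everything
is carefully normalized. `irlncpair` implements the *relative-ordering*
alternative for immune-related long noncoding RNAs (lncRNAs): the feature for
a pair of lncRNAs (A, B) in a sample is simply

```
S_{A|B} = 1  if expression(A) > expression(B) in that sample, else 0
```

which is invariant to any strictly monotone per-sample transform of the data
— no cross-sample normalization is required. The package is aimed at
computational biologists building or stress-testing survival signatures from
bulk tumour RNA-seq (the motivating application is bladder cancer with
TCGA-style cohorts of a few hundred tumours plus a handful of adjacent-normal
samples).

## What the pipeline does

1. **Screen** — immune-related lncRNAs (IRlncRNAs) by coexpression with an
   ImmPort-style immune gene list (Pearson |r| > 0.4, P < 0.001 on
   log2(x+1), tumour samples), then differentially expressed IRlncRNAs
   between tumour and normal (|log2FC| > 2, BH-FDR < 0.05).
2. **Pair encoding** — the 0/1 matrix over all C(m,2) canonical pairs of DE
   lncRNAs; pairs whose majority value exceeds 80% of samples are deleted
   (they carry no discriminative information).
3. **Signature** — 1:1 event-stratified train/test split; univariate Cox per
   pair; Lasso-penalized Cox with seeded 10-fold cross-validation (penalty
   minimizing the held-out partial-likelihood deviance); bidirectional
   AIC-stepwise multivariate Cox. The risk score is the Cox linear
   predictor `Risk = Σ_i β_i · S_i`.
4. **Dichotomization** — time-dependent ROC (Kaplan–Meier estimator) at 1, 3
   and 5 years; the high/low-risk cutoff minimizes the AIC of a univariate
   Cox fit on `score > c` over the 1-year ROC candidate grid, estimated on
   the training set and reused unchanged everywhere.
5. **Validation** — Kaplan–Meier/log-rank split, univariate and multivariate
   Cox against clinical covariates, ROC comparison with clinical traits,
   chi-square association with clinicopathology.
6. **Immune/drug associations** — Spearman correlation of the risk score
   with immune-infiltration estimates (lollipop table), rank-sum tests of
   immune-checkpoint gene expression and predicted drug IC50 between risk
   groups (BH q-values reported alongside raw p).
7. **Subtypes** — Monti consensus clustering of tumours on the signature's
   pair features (average-linkage on Hamming distance, 100 × 80%
   subsampling), cluster-number diagnostics (CDF delta-area, PAC), PCA
   verification, and cluster-level survival / microenvironment-score /
   checkpoint comparisons.

A first-class synthetic-cohort generator (`irlncpair.datasets`) plants all
of this structure — coexpression, differential expression, pair-driven
proportional hazards with calibrated censoring, clinical associations,
subtypes, infiltration/IC50 effects — with known ground truth, so the whole
pipeline is testable end-to-end without any download.

## Worked example

Simulate a cohort (200 tumours, 12 normals, 4 planted prognostic pairs,
three subtypes) and run the full analysis:

```bash
irlncpair simulate -o demo/cohort --seed 7 --config sim.yaml   # CohortConfig overrides
irlncpair run -c demo/run.yaml -o demo/run                     # paths + thresholds + seed
irlncpair report -o demo/run
```

Output of `report` (abridged):

```
cohort: 200 tumour / 12 normal samples
immune-related lncRNAs: 40; DE: 25 (20 up / 5 down)
pairs: 300 total, 86 after constancy filter
selection: 27 univariate -> 8 lasso -> 4 final

final signature (pair, beta):
  LNC0001|LNC0005           +0.6630
  LNC0002|LNC0003           -0.9323
  LNC0004|LNC0005           +0.8324
  LNC0004|LNC0019           +0.5415

AUC train   @  365d: 0.754
AUC test    @  365d: 0.775
log-rank entire : chi2=91.44, p=1.15e-21
cutoff: 1.2393; high-risk n=67
clusters: k=3
```

Reading this: the screen found 25 DE immune-related lncRNAs (20 up in
tumour); of 300 possible pairs, 86 were informative; the selection cascade
kept 4 pairs whose 0/1 orderings carry the survival signal (two of the four
planted pairs appear exactly, with the planted signs; the other two selected
pairs share planted member genes, whose orderings are nearly collinear with
the planted ones in this clustered cohort). A patient's risk score is
the β-weighted sum of their orderings; scores above the AIC-chosen cutoff
1.24 define the high-risk group, which separates sharply on Kaplan–Meier
(log-rank p ≈ 1e-21). Consensus clustering on the signature pairs recovers
the three planted subtypes.

The same stages are available as library calls (`coexpression_filter`,
`differential_expression`, `encode_pairs`/`filter_pairs`, `build_signature`,
`td_roc`/`aic_cutoff`, `consensus_cluster`, …) and as sklearn-style
estimators (`PairEncoder`, `PairedCoxSignature`, `RiskStratifier`,
`ConsensusCluster`) that compose with sklearn tooling.

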