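# Methods

This note documents the statistical model behind `irlncpair`, the choices
made where the procedure was genuinely open, the synthetic-cohort generator
and its calibration, and the limitations of both.

## The pair-signature model

For lncRNAs A, B and sample s the feature is `S_{A|B}(s) = 1[x_A(s) > x_B(s)]`
with ties scoring 0 and orientation fixed canonically (A before B by gene-id
sort). Because `S` depends only on the within-sample ordering, it is exactly
invariant to strictly monotone per-sample transforms — the property that
makes the signature portable across normalizations and batches (asserted as
an exact-equality test under random per-sample power/scale/shift maps).
A pair whose majority value exceeds 80% of tumour samples is nearly constant
and is deleted; the boundary (one-frequency exactly 0.2 or 0.8) is kept, and
both bounds are configurable since a literal reading of the deletion rule
("greater than 80%") fixes the boundary only up to convention.

The risk model is a Cox proportional-hazards linear predictor over selected
pairs, `Risk(s) = Σ_i β_i S_i(s)`. Selection is a three-stage cascade on the
training half of the cohort:

1. **Univariate Cox screen** at Wald p < 0.05 per pair. The threshold is a
   convention of this literature — the procedure is usually reported without
   one — and is configurable. Constant pairs are skipped and logged.
2. **Lasso-Cox** (elastic-net path, l1 ratio 1) with seeded 10-fold CV. The
   penalty minimizes the Verweij–van Houwelingen cross-validated deviance
   `−2[logPL_all(β_k) − logPL_train(β_k)]` (Breslow likelihood, matching the
   path solver). The deviance-minimizing penalty (not the 1-SE rule) is the
   default because it maximizes selection power at the cohort sizes used
   here. An optional repeated-subsample mode (fit on random 80% subsamples,
   keep pairs selected in a configurable fraction of repeats) is available
   via repeated calls with derived seeds for users who want a
   stability-selection variant.
3. **Bidirectional AIC-stepwise Cox** starting from the full Lasso-survivor
   model (drop and add moves; a move is accepted only if it lowers the AIC,
   so accepted AIC is non-increasing). Whether the original procedure was
   forward, backward or both is unstated; bidirectional-from-full is the
   stepwise-AIC default of the surrounding software ecosystem. Non-converging
   candidate models are treated as invalid moves; if the starting model
   itself does not converge, the weakest covariate (largest univariate p) is
   pruned until it does.

The nesting `final ⊆ lasso survivors ⊆ univariate survivors` is asserted on
every build.

### Cox fitting

`cox_fit` delegates to lifelines (Efron tie handling; Breslow selectable)
and then polishes the solution with full Newton steps on the Efron partial
likelihood to machine precision, because lifelines' soft stopping rule can
leave ~1e-6 residual error near flat optima. AIC is `2k − 2·logPL`. For the
large univariate scans (thousands of one-covariate fits) a dedicated
single-covariate Newton solver (`cox1`) avoids per-fit fitter overhead; it
is cross-validated against lifelines in the test suite. Monotone likelihood
(separation) is detected (coefficient escaping past |β| = 30 or a
degenerate Hessian) and returned as a flagged, non-converged fit rather
than silent numbers.

### Time-dependent ROC and the cutoff

The ROC at horizon t uses the Kaplan–Meier estimator (Heagerty–Lumley–Pepe):

```
Se(c,t) = [1 − Ŝ(t | X > c)] · P(X > c) / [1 − Ŝ(t)]
Sp(c,t) =      Ŝ(t | X ≤ c) · P(X ≤ c) /      Ŝ(t)
```

clipped to [0,1]; the AUC is the trapezoid over the (1−Sp, Se) polyline
after adding the (0,0)/(1,1) endpoints and sorting (the KM estimator can be
locally non-monotone). The KM method was chosen over the nearest-neighbour
smoother because it is fully specified without a bandwidth. Estimates are
snapped to 12 decimals before sorting: float jitter in the KM products must
not disorder the staircase, since without censoring the curve reduces
*exactly* to the empirical ROC and the AUC to the Mann–Whitney statistic
(asserted to 1e-10 on random instances). Default horizons are 365/1095/1825
days; all clinical time is kept in days.

"AIC of each point of the 1-year ROC" is operationalized as: candidates are
midpoints between consecutive sorted unique training scores; each candidate
is scored by the AIC of a one-parameter Cox fit on `1[score > c]` over the
full follow-up (the only AIC definable at a single ROC point; the 1-year
horizon fixes the ROC on which candidates are reported). Candidates with
non-identified dichotomizations (monotone likelihood, e.g. an extreme cutoff
isolating a censored-only group) are excluded. Youden's J at the horizon is
available as an alternative rule, and the two agree on cleanly separated
bimodal scores. Boundary scores equal to the cutoff go to the low-risk
group; the training cutoff is reused verbatim on test and entire sets.

### Downstream statistics

Stage/grade enter Cox and ROC comparisons as ordinals (I<II<III<IV,
low<high), age numeric, sex binary; complete-case per analysis with dropped
counts logged. Chi-square tests are uncorrected by default (Yates optional)
with a low-expected-count diagnostic. Between-group expression/IC50
comparisons use the Mann–Whitney rank-sum test: the source procedure names
the signed-rank test, which is inapplicable to independent groups — this
deliberate substitution is the package's documented reading. All association
families report BH q-values next to raw p and let the user filter on either.

### Consensus clustering

Monti resampling: 100 repetitions, each subsampling 80% of tumours without
replacement, clustered by average-linkage hierarchical agglomeration on
Hamming distance of the binary pair features (natural for 0/1 data and the
hclust-style default of the source ecosystem); consensus(i,j) =
co-clusterings / co-samplings. Final labels cut the average-linkage tree of
1 − consensus. The consensus-CDF area is computed as `1 − mean(consensus)`
(the exact area under the empirical CDF on [0,1]); delta-area is
`A(2)` at k=2 and `(A(k) − A(k−1))/A(k−1)` beyond, with k chosen by maximum
delta-area unless fixed (the replication profile fixes k = 3). PAC
(proportion of consensus values in (0.1, 0.9)) is reported as a diagnostic.
Repetitions, subsample fraction, linkage and distance are assumptions — the
original report states none of them.

## The synthetic cohort generator

`generate_cohort` draws log2-scale expression `N(μ_g, σ_g)` (μ ~ U(3,8),
σ ~ U(0.6,1.2)), exponentiated to the linear scale for output. Structure is
planted as follows, with every element recorded in a `GroundTruth` object:

- **Coexpression**: each coexpressed lncRNA loads on its immune partner's
  latent factor with loading `r·σ_total`, giving population Pearson
  correlation exactly `r` (default 0.6, comfortably above the 0.4 screen).
- **Differential expression**: tumour means shift by ±`de_log2fc` (default
  3.0 against the screen's 2.0). Defaults plant 81 up- and 15 down-regulated
  lncRNAs in a 300-lncRNA panel, mirroring a TCGA-bladder-scale cohort of
  394 tumour / 18 normal samples.
- **Prognostic pairs**: members of a planted pair share mean and σ, so the
  pair's one-frequency is near 0.5 and survives the constancy filter. Default:
  four pairs with |β| = 0.8, alternating sign.
- **Survival**: exponential baseline (constant h₀ = 1/1500 per day, chosen
  to give a realistic ~25% one-year mortality) with hazard
  `h₀·exp(Σ β_i S_i + γ_cluster)`; the S_i are computed from the realized
  expression orderings, so the generative model is exactly the model the
  pipeline fits. Censoring is independent uniform on (0, c_max) with c_max
  bisected against the drawn event times to hit the target censoring
  fraction (default 30%, realized within a fraction of a point).
- **Subtypes**: cluster c shifts the members of its assigned pairs by
  ±`cluster_sep`/2 so the expected ordering flips between clusters. Shifts
  are centred over tumour samples (log2FC stays exact) and their variance is
  folded into the member genes' variance budget — the gene's total σ is
  widened to `max(σ_g, 1.02·sqrt(v_cluster/(1−r²)))` and the latent loading
  rescaled — so the planted coexpression correlation survives the cluster
  structure. Optional per-cluster log-hazard offsets plant survival
  differences between subtypes.
- **Clinical covariates**: stage/grade/T/N/M drawn from logistic models on
  the standardized true risk (default slope 0.8 log-odds per SD), age and
  sex independent.
- **Infiltration / ESTIMATE / IC50 tables**: infiltration scores are
  `sign_ct·a·z_risk + √(1−a²)·noise` per cell type × method (a = 0.5 by
  default; CD4 T and NK cells planted negative); microenvironment scores
  shift by cluster; half the drugs' IC50s are associated with risk,
  alternating direction.

Everything is drawn from one `numpy` Generator seeded by `config.seed`;
identical configs are byte-identical on disk. Infeasible configurations
(pairs without DE members, overlapping pair members, censoring target ≥ 1…)
raise a configuration error.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: RNA-seq counts and library-size effects (values
are log-normal, not negative binomial), batch effects (ironically the
motivation for rank pairs), correlated gene modules beyond the planted
latents, non-proportional hazards, competing risks, and informative
censoring. Recovery results on these cohorts are a best case for the
selection cascade, not an estimate of its behaviour on TCGA.

## Problem sizes and numerical choices

Tests and the acceptance script use scaled lncRNA panels (40–60 lncRNAs,
150–400 tumours) so the full cascade runs in seconds per cohort; the planted
effect sizes, censoring and thresholds are kept at the defaults above. The
full-scale configuration (394 tumours, 96 DE lncRNAs, 4560 pairs) is
exercised once, end-to-end including the file round-trip, in
`scripts/acceptance.py`.

Numerical conventions not covered above: expression is assumed linear-scale
on disk and log2(x+1) is applied internally where a log scale is required;
clinical rows with non-positive follow-up are dropped on read (counted and
logged); correlation screening skips zero-variance genes with a warning;
stage seeds derive from the master seed as `(seed·1_000_003 + stage) mod 2³¹`.

## Known limitations

- With planted subtypes, pair orderings of shared member genes are nearly
  collinear; the Lasso/stepwise stages may then select a proxy pair instead
  of a planted one. Recovery statistics are therefore defined on
  single-cluster cohorts.
- At four pairs with |β| = 0.8 the population 1-year AUC of the *true*
  score is ≈ 0.73 at the default hazard; estimated training AUCs scatter
  around that ceiling. Stronger discrimination requires more pairs or larger
  coefficients, as in the 13-pair and |β|>1 regimes the method targets in
  practice.
- The AIC-on-ROC cutoff rule is one defensible reading of a procedure whose
  original description is ambiguous; Youden is provided as the alternative.
- Delta-area k-selection is reliable when planted clusters are equidistant;
  for asymmetric cluster geometries PAC is the more stable diagnostic and is
  always reported.
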