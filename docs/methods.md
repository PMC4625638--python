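# Methods

## Scope and data model

`omicox` compares the prognostic power of four genomic data sources —
mRNA expression (EXPR), miRNA expression (MIRNA), segmented copy-number
values (CNA), binary somatic mutation calls (MUT) — and their
row-concatenation (MERGE) for censored survival prediction.  A cohort is
a set of feature-by-patient matrices sharing one patient order, a
clinical table of positive follow-up times with 0/1 event indicators, an
undirected gene-interaction network, and a miRNA→target map.  Times are
abstract positive reals (days by convention); no clinical date handling
is attempted.  Patient alignment intersects the id sets of all inputs
and orders them lexicographically, so outputs never depend on file
order.

## Cox core

All model fitting maximizes the Efron-tie-corrected Cox partial
likelihood with damped Newton iterations.  Numerical choices:

- convergence when max |score|/n < 1e-7, at most 100 iterations, with
  step-halving (up to 15 halvings) whenever a full Newton step would
  decrease the likelihood;
- a 1e-8 ridge on the observed information, so collinear or separated
  covariates (common in sparse binary mutation data) yield finite,
  flagged (`converged=False` where the score criterion fails) fits
  instead of divergence;
- iteration also stops when the likelihood improves by < 1e-10 — the
  plateau reached under complete separation.

The implementation is vectorized over deaths (suffix risk-set sums plus
per-tie-group corrections) because the selectors perform 1e4–1e6 small
fits per run; it agrees with lifelines' `CoxPHFitter` to ~1e-5 in the
coefficients (the difference is the convergence tolerance) including on
tied event times.

### Evaluation statistics

- **c-index** (Harrell): usable pairs are those whose times differ and
  whose earlier time is an event; tied prognostic indices score 0.5.
  Pairs with exactly tied times are unusable — the classic definition
  ("the smaller time is an event") has no reading for them.  Censoring-
  weighted variants (Uno) are out of scope.
- **Log-rank median split**: low risk = index ≤ median, high = index >
  median (the single ≤/> convention used across the package, including
  the CNA filter).  The two-group test delegates to
  `lifelines.statistics.logrank_test`; significance tiers are a/b/c for
  p < 0.05/0.01/0.001.
- **Cohen's kappa** on the two binary risk groupings; when both raters
  are constant the chance agreement is 1 and kappa is reported as NaN.
- **Protocol**: one event-stratified split assigns round(2/3 · stratum)
  patients per stratum to training.  Stratified bootstrap resamples
  within event strata, preserving the event count exactly.  CPSO/NFS
  models on continuous data are evaluated on the blind-test third;
  LASSO models and all mutation-trained models by resubstitution
  (training samples of sparse binary data can otherwise contain no
  mutated patient for a gene).

## Filters

- EXPR/MIRNA: first a correlation filter — keep a feature iff its
  largest absolute Spearman correlation with *any other feature of the
  same matrix* exceeds 0.6 (correlating against censored survival times
  is ill-defined, so partners are other features); then a quantization
  filter — cut each feature's observed range into 5 equal-width bins and
  keep features occupying ≥ 3 bins (constant features occupy one and are
  dropped).  Binning is per feature, not global.
- CNA: per feature, a univariate Cox fit, median split of the prognostic
  index, log-rank p-value; keep the ceil(fraction · p) smallest p-values
  (default fraction 0.10); non-converging fits rank last; ties break by
  feature id.
- MUT: keep the ceil(fraction · p) most frequently mutated genes, ties by
  feature id.  The fraction is a plain configuration value (it was
  cohort-specific in the original study, with no stated rationale).

Fraction-to-count conversion always uses the ceiling so a positive
fraction never keeps zero features.

## Selectors

**CPSO.**  Particles live in a continuous k-dimensional box over the
feature-index range.  Decoding rounds each coordinate and repairs
duplicates by advancing upward (wrapping) to the nearest unused index.
Velocity update `v ← w·v + c1·r1·(pbest − x) + c2·r2·(gbest − x)` with
w = 0.72, c1 = c2 = 1.49 (standard constriction-style defaults), v
clamped to ±0.25 of the index range, positions clamped to the box; bests
update on strict improvement.  Fitness is the mean c-index over
stratified-bootstrap refits; within one run the bootstrap resamples are
fixed, so fitness is a deterministic, memoizable function of the decoded
subset — this is what makes desk-scale runs cheap.  Defaults follow the
reference protocol (k = 5, 500 iterations) except `runs`, where the desk
default is 20 (the original used 1 000); the final model is refit once,
unpenalized, on the training set.

**NFS.**  Singleton models (univariate Wald p-values; failures degrade to
p = 1) grow by one eligible neighbor per step: a network neighbor of any
member, not already in the model, present in the data, and with degree
within the hub limit (default 1 000).  Hub genes are not allowed to grow
— they are neither added nor expanded through.  Candidates are
deduplicated, scored by the likelihood-ratio p-value of the multivariate
fit against the null model (the growth "performance" metric was a free
choice; the LRT extends the univariate p-value criterion naturally), and
the top ceil(0.05 · candidates) survive globally (not per parent).  Two
desk-scale controls: growth runs for at most `max_iterations` (10)
generations, and `max_models` (default 100) caps survivors per
generation — without the cap the survivor count grows roughly
geometrically on dense networks (observed 32→571 in six generations on a
160-feature metabase); `max_models=None` restores the uncapped rule.
The best-scoring model seen at any generation is returned.  Surrogate
miRNA networks give each miRNA the union of its target genes' edges; on
MERGE data gene edges apply to every source's feature carrying that gene
id.

**LASSO.**  The elastic-net penalized Cox path (mixing parameter default
1.0 = pure lasso, configurable since the original description is
ambiguous between lasso and elastic net) is computed by scikit-survival's
coxnet coordinate-descent solver on internally standardized covariates;
coefficients are returned on the original scale and satisfy the KKT
subgradient bound (checked in the tests).  Model choice: per lambda, the
Verweij–van Houwelingen cross-validated deviance
−2·(ll(all; β_fold) − ll(train; β_fold)) over event-stratified folds;
the chosen lambda is the one whose active set is closest to the target
size (default 10, "around ten features"), ties broken by better CV
deviance; an all-empty path reports "no model generated".  The final
model is refit unpenalized on the active set.

## Synthetic cohorts

The generator emulates a TCGA-style multi-platform cohort:

- A standard-normal latent risk factor u per patient.  Planted features
  load on u (default loading 0.7); the hazard is proportional to
  exp(η) with η the linear predictor over all planted features.  The
  shared latent is deliberate: in real tumours CNA, mRNA and miRNA
  readouts partially reflect the same biology, and without cross-source
  correlation the agreement analyses would be vacuous (independent
  sources give kappa ≈ 0 at any censoring rate).
- EXPR/MIRNA: co-expression modules of four features sharing a module
  factor (pairwise ρ ≈ 0.64) over two thirds of features, the rest
  independent; each planted gene gets one co-regulated partner
  (ρ ≈ 0.8).  This is what gives the correlation filter realistic
  retention.  CNA: blocks of four consecutive features share a latent
  segment value, mimicking segmented (regionally correlated) output.
  MUT: per-gene frequencies uniform on the configured range (default
  0.02–0.3); planted genes' mutation probability rises with u on the
  logit scale.
- Event times are Weibull with configurable shape (default 1 =
  exponential): T = scale · (E/exp(η))^(1/shape), E ~ Exp(1), scale
  default 365 days.  Censoring is exponential; its rate is calibrated by
  bisection of the expected censoring fraction
  mean_i(1 − exp(−rate·t_i)) against the realized event times, which is
  monotone in the rate.  Target 0 means no censoring.  The censoring
  family itself is a free choice (the original study reports only event
  proportions).
- The interaction network is a Barabási–Albert graph over the expression
  gene ids (attachment parameter default 2) with the node→gene assignment
  shuffled; planted genes are rewired into one connected chain so the
  network selector can recover them; an optional hub of configurable
  degree supports hub-exclusion tests.  Mutation features reuse the gene
  namespace, so MERGE-mode growth across sources is exercised.  Every
  miRNA targets 1–3 expression genes; planted miRNAs also target a
  planted gene.
- All randomness flows from one seed through a single named generator;
  every matrix shares the clinical table's patient order.

What the generator does **not** emulate: platform artifacts (probe and
batch effects), methylation data, non-proportional hazards, and
competing risks.  Passing recovery tests therefore show that the
selectors find planted proportional-hazards signal under realistic
censoring — not that they are robust to real-data artifacts.

## Experiments and problem sizes

- *Recovery*: 20 cohorts of n = 300 patients, 30 % censoring, strong
  planted effects (1.2/1.0/0.8 log-hazard on expression); each selector
  trains on the two-thirds split and is scored on the blind third.
  Desk-scale selector settings: CPSO runs = 2, 40 iterations, swarm 15,
  B = 5, k = 3; LASSO target size 5, 5 folds; NFS defaults.
- *Censoring/agreement*: per seed one uncensored cohort (n = 250,
  moderate effects — oracle c-index ≈ 0.7, the range reported for real
  cohorts; saturated signal would make identification insensitive to
  censoring) with each censoring level applied to the same event times,
  so cohorts are matched except for censoring.  One penalized-Cox model
  per continuous data type; mean Cohen's kappa over cross-data-type
  pairs of median-split risk groups; the 0-vs-0.8 contrast is judged by
  a one-sided sign test over 20 seeds.

## Reporting conventions

Tables display c-index × 100; margins are arithmetic means over
populated cells, rounded half-up (the published table itself rounds
inconsistently in two 0.5 cells, so worked-example comparisons allow
±1).  Source-share percentages round half-up to integers; rounding can
make a percentage column sum to 100 ± 2.  The bundled published
summaries carry a printed overall model-size total of 216 whose own
column sums give 108; the utilities report the true sum and this note
records the discrepancy.  Cells whose selector produced no model are
rendered "-" and excluded from margins and kappa matrices.

## Known limitations

- NFS's beam cap and the desk-scale CPSO run counts are pragmatic
  bounds; uncapped, cluster-scale settings are configuration away but
  untested here.
- The c-index ignores tied-time pairs; datasets dominated by heavily
  tied times will have few usable pairs.
- The LASSO path inherits coxnet's Breslow tie handling while refits use
  Efron; with continuous times the two coincide.
- Real post-filter feature counts and per-cohort c-index values from the
  original TCGA analysis depend on data this package does not ship and
  are not reproduced.
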