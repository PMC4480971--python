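# Methods

## Model and workflow

The framework regresses log2(IC50) on baseline log2 expression with
2-component PLS1 (columns centered and scaled to unit variance before
fitting; zero-variance columns are dropped and logged). PLS is preferred
over ordinary regression because the predictor count far exceeds the
sample count and genes are collinear; only the first two latent components
feed the per-gene weight w = sqrt(L1^2 + L2^2), which drives consensus
ranking and forward selection. The number of components is configurable
(`n_components`); two is the default everywhere.

Model robustness comes from resampling rather than internal sparsity: the
panel is split n_outer x n_inner times (tertile-stratified 70/30 outer,
uniform 60/40 inner; overall 42/28/30 percent random-training /
random-validation / balance-validation), every split is fitted and scored,
and outer sets are ranked by five criteria. Three of those criteria are
described only qualitatively in the literature this design follows, so
their quantitative forms here are package choices:

- C2 (correlated metrics): Spearman correlation between inner-split
  random-validation correlation and AUC; a constant metric (AUC pinned at
  1 when classes separate perfectly) scores 0 because it carries no
  ranking information.
- C3 (narrow balance spread): IQR(balance-val corr) / IQR(random-val
  corr) must be < 1.
- C4 (non-inferiority, i.e. no over-fitting): balance-validation medians
  of both metrics must be within delta = 0.02 of the random-validation
  medians. The delta is configurable; 0.02 is small relative to the
  metric spread at panel sizes of 100-200.
- C5 (absolute performance): median balance-val corr + median balance-val
  AUC; survivors are ranked by C5, ties by C2. "Good random-validation
  performance" (criterion 1) is absorbed by C5 and by the choice of the
  best inner model per set rather than enforced as a separate numeric bar.

Top-model redundancy is controlled by the Jaccard similarity of
random-training line sets against the 90% quantile of a Monte-Carlo null
(two uniform random subsets of the same size; 10,000 draws). Filtering is
greedy in rank order, so the better-ranked member of an overlapping pair
survives; this makes the retained set deterministic given the ranking.

Consensus weights are the first right singular vector of the stacked
per-model weight vectors (each normalized to unit norm and zero-filled
onto the union gene universe), sign-oriented to non-negative mean
correlation with the rows. The SVD is applied to the combined
sqrt(L1^2+L2^2) weights, not per component: the weight vector is what the
downstream ranking consumes, and it is invariant to per-component sign
indeterminacy. Forward selection retrains the representative split's model
at sizes k = 5, 6, ... and stops at the smallest k whose correlation and
AUC both fail to improve by more than eps = 0.005 anywhere in the next 10
sizes (`forward_eps`, `forward_window`); if no plateau occurs the full set
is returned with a warning rather than silently truncating.

Pathway filtering uses the one-sided hypergeometric tail with the
post-reduction gene universe as background; the gate is raw p < 0.01 (BH
values are reported but do not gate, keeping the selection consistent with
the raw-p feature gate). Any GMT collection can be supplied. If no pathway
is significant the core signature is used unchanged (logged), so the
pipeline degrades gracefully instead of failing.

## Cutoffs and class conventions

- Sensitive = score strictly below the cutoff; a score exactly at the
  boundary is resistant. One deterministic rule applied everywhere
  (training calibration and patient classification).
- Response cutoffs: sample median for normal-like distributions; for
  bimodal ones the argmin of a Silverman-bandwidth Gaussian KDE between
  the two highest-density modes. `auto` chooses the valley only when the
  KDE has >=2 modes and at least 10% of the data lie on the minor side;
  requesting a valley on a unimodal sample is an error that names the
  alternatives. A manual override is kept for score distributions without
  a clean separation point.
- Middle-tertile removal (drop the floor(n/3) middle lines by IC50 rank)
  applies only to normal-like panels, where the middle of the
  distribution is ambiguous by construction; bimodal panels pass through
  unchanged.
- Responders are patients with PFS >= the drug-specific cutoff (boundary
  counts as responder). Undefined confusion ratios (zero denominators)
  are reported as not-available, never coerced to 0.

## Cross-platform transfer

Patient cohorts are mapped through a best-match probe table (each source
probe maps to at most one target; duplicate targets resolve by the
probeset-collapsing rule: highest mean, then higher variance, then lexical
id) and quantile-normalized against the training panel before any
signature subsetting. The reference distribution is the per-rank mean over
reference samples; ties receive the mean of the tied ranks' reference
values, and unequal feature counts interpolate the reference distribution
at the test quantile positions. Normalizing on the whole shared feature
space is what licenses carrying the training-panel score cutoff onto the
cohort unchanged.

## Statistical components

- Fisher transform f = 0.5*ln((1+r)/(1-r)); the permutation null shuffles
  the response vector once per iteration for all genes jointly, preserving
  gene-gene correlation under the null. Permuted f-values are summarized
  by sample mean/SD and the two-sided p comes from the fitted normal. The
  null SD tracks the asymptotic 1/sqrt(n-3).
- BH adjustment via the standard step-up procedure (statsmodels).
- ROC AUC equals the Mann-Whitney pair statistic with ties counted 1/2;
  lower predicted IC50 means predicted sensitive.
- Survival: Kaplan-Meier medians, two-group log-rank test and a
  univariate Cox model (lifelines). Lifelines handles ties by Efron's
  method, which is at least as accurate as Breslow's with the monthly-PFS
  ties encountered here; hazard-ratio confidence intervals are Wald.
- Genetic-event association: Pearson r of the binary event vector with
  log2 IC50 (positive = resistance-associated), a two-sided permutation p
  over 1000 response shuffles (add-one correction), and Fisher's exact
  test against the sensitive/resistant classes.

## The synthetic study generator

The generator emulates the statistical structure of a screen, not its
biochemistry. Per gene: baseline ~ N(7, 1.5^2) log2 units (drivers
N(9, 1^2): informative markers are well expressed), residual SD ~
U(0.6, 1.4). Drivers additionally load (+-0.8) on a latent pathway factor,
which makes them mutually correlated (|r| ~ 0.3) — the consensus and
pathway stages are only meaningful with correlated drivers — and
guarantees a driver variance floor of 1.0 so the variance-1 reduction
cutoff retains drivers by construction rather than by luck. log2 IC50 is
the weighted sum of driver deviations (weights +-`driver_effect_size`,
both directions, so the signature contains sensitivity- and
resistance-associated genes) plus N(0, `noise_sd`) noise; per-driver
correlation with response is ~0.5-0.6, a strong-marker regime. Bimodal
panels shift the latent factor of a random half of the lines so the gap
between IC50 modes equals `bimodal_gap` while expression and response stay
coupled.

Patient cohorts are fresh draws from the same expression model, shifted by
`platform_shift` and renamed to second-platform ids with a generated
best-match table (`map_fraction` controls mapping loss). PFS is
exponential with log hazard `pfs_link` x standardized true score and
baseline median 3 months; censoring is independent uniform administrative
censoring hitting `censor_rate` of patients in expectation. The default
pfs_link = 1.5 is chosen so that a perfectly informed classifier's
accuracy ceiling against PFS dichotomized at 2.4 months is ~85%:
dichotomized exponential survival is intrinsically noisy, and a weak link
would cap accuracy near 60% regardless of model quality, which is not the
regime this kind of biomarker operates in. Dose-response curves are
4-parameter-logistic-like sigmoids over a 10-dose 3-fold dilution series
with planted QC violations and a truth column naming the violated rule.

Two-drug studies draw disjoint driver blocks riding on independent latent
factors over the same panel, so each signature should predict only its own
drug — the desk-scale analogue of drug specificity.

What the generator does **not** emulate: probe-level noise, batch
structure beyond a global platform shift, copy-number or mutation
mechanisms (events are plain binary vectors), non-proportional hazards,
and indication-specific expression differences (indication labels are
assigned round-robin). Passing tests therefore demonstrate that the
pipeline recovers planted structure under idealized noise, not that it
will perform identically on real screens.

## Problem sizes and determinism

The reference simulation used by the test suite and the acceptance script
is 2,000 genes / 30 drivers / 200 cell lines with a 10x100 split ensemble
(1,000 fitted models) — large enough that every stage, including the
five-criteria set ranking and overlap filtering, operates away from
degenerate small-sample corners, while a full run stays under a minute.
The two-drug specificity study uses 500 genes / 12 drivers per drug / 150
lines with a 3x30 ensemble, averaged over five seeds.

All randomness flows from explicit seeds. Split seeds are counter-derived
([master, outer] and [master, outer, inner]), so any single split — and
hence any top model — can be re-fitted in isolation without storing the
150,000-model ensemble; only the per-split metric table is held in
memory. Re-running any stage with the same configuration reproduces its
artifacts bit for bit, and the final signature JSON records the seed and
a configuration hash.

## Known limitations

- The five selection criteria are operationalizations of qualitative
  descriptions; different quantitative forms (e.g. a hard criterion-1
  threshold) would select different top sets.
- The plateau rule depends on eps/window; very flat performance curves
  can plateau before all informative genes enter, and strictly rising
  curves return the full set.
- With strong planted signal the validation AUC saturates at 1, making
  C2 uninformative (scored 0); real screens with weaker signal exercise
  C2 more.
- Quantile normalization assumes the cohort and panel share a global
  expression distribution up to monotone distortion; it cannot correct
  feature-specific platform effects.
- The Cox model is univariate by design; no covariate adjustment.
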