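# Methods

This note records the model, the generator, and every numerically
consequential choice made where the published description leaves the
design open. Nothing here asserts an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Task and data model

Binary classification on a patient-by-feature table: 20 clinical
variables of mixed type (continuous, e.g. age, BMI, CA-125; binary, e.g.
BRCA1/2 status; small counts, e.g. number of affected relatives), outcome
1 for the *rare class* (occult adnexal tumor found at RRSO, prevalence
7.6%: 14 of 184, 6 STIC + 8 invasive) and 0 for controls. Missing values
occur in 10 of the 20 features (2–10% per feature).

## Preprocessing

**Imputation.** For each patient with missing values, the donor is the
fully-observed patient minimizing Euclidean distance computed over
exactly the recipient's observed features, on raw (unstandardized)
values; all of the recipient's missing cells are copied from that single
donor. Consequences worth knowing:

- The distance mixes scales: CA-125 (tens of UI/ml) dominates age (years)
  and 0/1 indicators. This mirrors the published sequencing (imputation
  precedes standardization); a scale-free variant would change donors.
- One donor per recipient, not per-feature nearest donors: the published
  description refers to "the patient … whose feature vector had the
  minimum distance", singular.
- Ties between equidistant donors resolve to the smaller row index
  (deterministic) and are flagged on the imputation record.
- Imputed values are always observed values (copies), so imputation is
  idempotent.

**Standardization.** Continuous features only; mean removed and scaled by
the population (ddof = 0) standard deviation; binary and count features
pass through. Default mode standardizes once on the entire cohort before
cross-validation, reproducing the published order of operations; this
leaks the held-out patient's value into the scaling parameters, so a
`train-only` mode (parameters refit on each fold's remaining patients) is
available behind a config flag. A zero-variance continuous feature is an
error naming the feature.

## The backbone (one sub-model)

1. **Selection.** Mean-decrease-in-impurity (Gini) importances from a
   100-tree random forest; a feature is kept iff its importance is
   *strictly* greater than the median importance (ties at the median are
   dropped). With an even number of all-distinct importances this keeps
   exactly half. If the strict rule keeps nothing (all importances tied,
   e.g. all features constant) the model falls back to all features and
   warns. The forest is implemented in-package (numba-compiled CART:
   bootstrap per tree, sqrt(p) candidate features per node, per-tree
   importances normalized then averaged) because the calibration
   simulations fit hundreds of thousands of forests on 28–56-row training
   sets, where per-call overhead of a general-purpose implementation
   dominates; agreement with scikit-learn's RandomForestClassifier
   importances is asserted in the test suite.
2. **Scoring.** Soft-margin linear SVM, C = 1, solver tolerance 1e-4
   (libsvm SMO via scikit-learn; the publication names no
   hyperparameters, so these are fixed and surfaced in `RunConfig`). The
   signed margin is mapped to [0, 1] by Platt calibration — a logistic
   sigmoid fit to the training margins by Newton's method with Platt's
   smoothed targets t₊ = (N₊+1)/(N₊+2), t₋ = 1/(N₋+2), which keeps the
   fit finite on separable training sets. Scores above 0.5 count as a
   rare-class vote. The SVM is unweighted: imbalance is handled entirely
   by the resampling design.

Determinism: a sub-model is a pure function of (training rows, seed).
Row *order* affects the bootstrap draws of the selection forest (true of
any bootstrap implementation), so only the SVM + calibration stage is
exactly permutation-invariant (verified to 2.5e-9 at solver tol 1e-8 with
the mask held fixed).

## Ensemble and voting

Per held-out patient and ratio r ∈ {1, 2, 3}: `n_models` = 100 training
sets, each containing all available rare patients (all 14 when the
held-out patient is abundant, 13 otherwise) plus r·N_rare abundant
patients drawn uniformly without replacement, independently across
sub-models (sets may overlap). Majority vote per ratio; a 50/50 tie
(possible with an even model count) resolves to the rare class — the
screening-oriented choice, maximizing sensitivity — and is logged. The
ratio score is the max over rare-voting sub-models' scores when the
majority is rare, else the min over abundant-voting sub-models' scores
(the agreeing subset, not all models). The final score is the mean of the
three ratio scores.

Seed scheme: `SeedSequence(master, spawn_key=(fold, ratio, k))`, k = 0
for the resampling plan and k = m+1 for sub-model m. Seeds are
position-derived, never draw-order-derived, so folds are independent and
any single sub-model can be re-derived in isolation.

## Evaluation

ROC over all candidate cuts (midpoints between adjacent distinct scores,
plus one cut below the minimum and one at the maximum) with the strict
rule *rare iff score > threshold*; trapezoidal AUC, which equals the
Mann–Whitney concordance P(s₊ > s₋) + ½P(=) (asserted against scipy in
the tests). The operating threshold maximizes Youden's J; ties resolve to
the lower threshold (favors sensitivity). G-mean is √(sens·spec): the
publication's formula prints the product without the root, but its own
numbers (57.1%, 85.3% → 69.8%) require the root. As published, the Youden
threshold is chosen on the same leave-one-out scores being reported — an
optimistic convention, replicated for fidelity and noted here.

The *original model* baseline keeps the backbone but trains one model per
fold on all remaining (imbalanced) patients, no resampling or voting. On
imbalanced data with signal this baseline is expected to underperform the
ensemble (and did, markedly, on the original cohort); the paired-seed
comparison in the test suite checks the direction at a scaled-down size.

## Explanations

For a linear model under feature independence the Shapley value is
exactly wᵢ(xᵢ − x̄ᵢ) against the training background (the kernel
estimator's limit), and the base value — the expected prediction with no
features known — is the margin at the training mean. The reported score
passes the margin through the (nonlinear) Platt sigmoid, so margin-space
contributions are rescaled by the secant slope of the calibration map
between base margin and evaluation margin; additivity
(base + Σφ = score) is then exact at every level, which is the invariant
the tests enforce (≤ 1e-6). Note the base value in score space is the
calibrated score *at* the mean margin, not the mean of calibrated scores
(the two differ by Jensen's gap; the former is what makes additivity
exact). Per ratio the vote-selected sub-model is explained — the
published account does not say which of the 100 models is explained, and
this is the only model whose score survives aggregation; averaging the
explanations of all 100 is available behind a flag (`average_all`)
without any claim of fidelity. The ensemble explanation is the
feature-wise mean over ratios, matching the soft vote, so a feature
pushing in opposite directions under different ratios nets out near zero.
Features outside a sub-model's selection mask contribute exactly 0.

## Feature statistics

Selection frequency: per ratio, the percentage of training sets (pooled
over folds × sub-models) in which the median rule retained the feature.
Significance frequency: the percentage with p < 0.1 by
Wilcoxon–Mann–Whitney (continuous and count features; exact for small
untied samples, tie-corrected normal approximation otherwise — scipy's
auto policy) or Pearson chi-square without continuity correction (binary
features). No multiple-testing correction, replicating the published
p < 0.1 rule. A feature with a single observed level gets p = 1; expected
cell counts below 1 warn but do not switch tests. Both conventions make
rarely-varying features (e.g. a 1.6%-prevalence indicator) structurally
conservative: their null rejection rate sits *below* the nominal 10%,
at the boundary of the 5–15% calibration band the acceptance check uses.
Within one cohort, frequencies are strongly correlated across training
sets (all sets share the same 14 rare patients), so null calibration is
only meaningful pooled across many generator seeds; the acceptance check
pools 9,000 training sets across 300 seeds.

## Synthetic cohort generator

Emulates the published cohort's *marginal* structure exactly as printed:

- **Continuous** features: piecewise-linear inverse CDF through
  (q₁, median, q₃), exponential tails of scale IQR/2 beyond the
  quartiles, truncated at a plausibility bound (age ≥ 18, BMI ≥ 14,
  menarche ≥ 8, CA-125 ≥ 0). Reproduces the printed quartiles without
  asserting a parametric family.
- **Binary** features: Bernoulli with the printed Yes/observed
  proportion (observed counts, not the n = 184 percentages, for rows
  with missing values).
- **Count** features: categorical on {0..4} with probabilities chosen to
  reproduce the printed median and quartiles robustly (for the pregnancy
  count, P = 0.18/0.22/0.42/0.12/0.06 keeps the sample median at 2 with
  high probability; cumulative-probability choices too close to 0.5 put
  the sample median on a knife edge).
- **Class structure**: exactly 14/184 rare (6 STIC + 8 invasive) in every
  draw — counts, not expectations. **Missingness**: exactly the printed
  NA count per feature, uniform over patients, never on the outcome.
- **Planted effects** (for recovery testing): continuous rare-class mean
  shifted by effect·IQR; binary rare-class log-odds shifted by the
  effect; count probabilities exponentially tilted by exp(effect·k).
  Effects are injected before missingness, so imputation sees attenuated
  signal. All effects zero gives an exact null (features ⊥ outcome).

What the generator does **not** emulate: inter-feature correlation (the
publication reports marginals only, so clinically coupled pairs such as
age and menopausal status are independent here), subtype-specific effect
structure (STIC vs invasive carry no distributional difference, matching
the single-rare-class model), and any real-world measurement error
structure. Passing recovery tests therefore demonstrate that the pipeline
detects *marginal* signal at realistic imbalance and sample size — not
that it would reproduce the original cohort's headline metrics, which
depend on the real joint distribution and are documented as reference
values only (AUC 71.1%, accuracy 83.2%, sensitivity 57.1%, specificity
85.3%, G-mean 69.8%, per-ratio AUCs 68.3/59.5/65.7%, baseline AUC 35.8%).

## Problem sizes used by the checks

Simulation-based checks run at deliberately scaled sizes chosen as this
package's own test-design choice: null calibration uses the full cohort
size (n = 184) with 10 sub-models per ratio and 10-tree selection forests
over 50 seeds (the null AUC does not depend on ensemble width or forest
depth); significance-level calibration pools 300 seeds × 30 training
sets; planted-signal recovery uses n = 60 cohorts with 8 rare patients,
10 sub-models per ratio, and a 2·IQR effect on CA-125; the structural
invariants run one full fold at the published defaults (100 sub-models ×
3 ratios = 300 models). `scripts/acceptance.py` uses 50 full-size
cohorts.

## Known limitations

- The proximity imputation is single-donor and deterministic; no
  uncertainty propagation (no multiple imputation).
- As-published standardization and Youden thresholding both reuse the
  full score set, giving optimistic bias relative to a fully nested
  protocol; the leakage-safe standardization mode is provided but is not
  the default, for fidelity.
- The max/min score-selection vote makes the ratio score an extreme
  statistic of 100 calibrated scores; it is well-defined but noisier than
  a mean, and the ensemble inherits that.
- Chi-square p-values on 2×2 tables with tiny expected counts are used
  as published; they are conservative there, and the significance
  frequencies of near-constant features should be read accordingly.
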