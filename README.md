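# ovrisk

Explainable, imbalance-aware risk prediction of **occult ovarian cancer in
BRCA-mutated patients undergoing risk-reducing salpingo-oophorectomy
(RRSO)** — a tested re-implementation of a multi-ensemble resampled
classifier for strongly imbalanced clinical tabular data, together with a
synthetic cohort generator that stands in for the (non-deposited) study
cohort.

## The problem and the model

In cohorts of BRCA1/2 carriers undergoing prophylactic RRSO, occult
adnexal tumors (serous tubal intraepithelial carcinoma, STIC, or invasive
carcinoma) are found in only ~7.6% of patients — a *rare class* of 14 in a
cohort of 184. A single classifier trained on such data collapses toward
the majority class; the pipeline here counters this with random
under-sampling ensembles:

- **Leave-one-out validation.** Each patient in turn is held out; models
  are trained on the rest.
- **Under-sampled sub-models.** For each held-out patient, 100 training
  sets are drawn per class ratio 1:r (r = 1, 2, 3): every available
  rare-class patient plus r·N_rare randomly chosen abundant-class
  patients.
- **Shared ML backbone.** On each training set, random-forest Gini
  importances (100 trees) are computed and features with importance above
  the median are retained; a linear SVM (C = 1) on the retained features
  yields a margin, mapped to a [0, 1] score by Platt calibration.
- **Majority vote per ratio.** The modal class of the 100 sub-models wins;
  the ratio's score is max(scores of rare-voters) if the winner is rare,
  else min(scores of abundant-voters).
- **Soft vote.** The final score is the arithmetic mean of the three ratio
  scores; the operating threshold maximizes Youden's
  J = sensitivity + specificity − 1 on the ROC curve. Reported metrics:
  accuracy, sensitivity, specificity, G-mean = √(sens·spec), and AUC.
- **Explanations.** Because each sub-model is linear, exact Shapley values
  are available in closed form: φᵢ = wᵢ(xᵢ − x̄ᵢ) against the training-set
  background. Per ratio the vote-selected sub-model is explained (its
  score is the one propagated); the ensemble explanation is the
  feature-wise mean over ratios, so base + Σφ = score holds at every
  level.

Upstream, missing values are filled from the nearest fully-observed
patient (Euclidean distance over the recipient's observed features) and
continuous features are standardized to zero mean / unit variance.

The published cohort is private, so its headline numbers (AUC 71.1%,
accuracy 83.2%, sensitivity 57.1%, specificity 85.3%, G-mean 69.8%;
baseline-without-resampling AUC 35.8%) serve as reference values only;
`docs/methods.md` discusses what is and is not checkable without the
original data.

## Worked example

```bash
ovrisk all --n 60 --n-rare 8 --seed 7 --n-models 10 --n-trees 25 \
    --effects effects.txt --explain-patients P0002 --out-dir out/
```

with `effects.txt` containing `ca125 = 2.0` (a planted 2·IQR shift on
CA-125 in the rare class). This run writes `out/metrics.json`:

```json
{
  "accuracy": 0.766667, "auc": 0.742788, "config_hash": "60a56517557b",
  "fn": 1, "fp": 13, "gmean": 0.810093, "sensitivity": 0.875,
  "specificity": 0.75, "threshold": 0.109333, "tn": 39, "tp": 7
}
```

meaning: at the Youden-selected threshold 0.109, 7 of the 8 planted
rare-class patients score above threshold (sensitivity 87.5%) at the cost
of 13 false positives among 52 controls (specificity 75.0%), with AUC
0.74 — the planted CA-125 signal is recovered at this small scale (n = 60,
10 sub-models per ratio; the acceptance suite's planted-signal checks at
the same cohort size measure AUCs between 0.92 and 0.98 on other seeds).
`out/explanation_P0002.txt` renders the patient-level force layout; for
this control patient the ratio-1:1 explanation starts

```
patient P0002 [ratio1]  score=0.044  base=0.466
  - ca125            -0.4792
  - pregnancy_nftd   -0.2119
  + bmi              +0.0996
  ...
```

i.e. the patient's low CA-125 pulls the score far below the base value
(positive contributions push toward the rare class).

Library use mirrors the CLI:

```python
import ovrisk
cohort = ovrisk.generate_cohort(ovrisk.default_config(seed=1))
complete, log = ovrisk.impute_missing(cohort)
result = ovrisk.loo_predict(complete, ovrisk.RunConfig(seed=1, n_models=10))
report = ovrisk.evaluate_predictions(result.scores, result.labels)
```

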