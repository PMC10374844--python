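"""Selection-frequency and significance-frequency aggregation across all
sub-model training sets.

Two complementary views of feature importance, pooled over every training
set of the run (folds x sub-models, per ratio):

* *selection frequency* — the percentage of training sets in which the
  Gini/median rule retained the feature (a multivariate notion);
* *significance frequency* — the percentage of training sets in which the
  feature separated the classes at p < 0.1 by a univariate test:
  Wilcoxon-Mann-Whitney rank-sum for continuous and count features,
  Pearson chi-square (no continuity correction) on the 2x2 class-by-level
  table for binary features.

No multiple-testing correction is applied — frequencies aggregate raw
p < 0.1 indicators.  A feature with a single observed level in a training
set gets p = 1 by convention; expected cell counts below 1 log a
small-sample warning but the chi-square test is still used.  Both
conventions make rarely-varying features conservative by construction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import KIND_BINARY, CohortTable
from .ensemble import RunResult

logger = logging.getLogger("ovrisk")

#: the published significance rule
P_THRESHOLD = 0.1


class ArtifactsMissingError(ValueError):
    """Run was executed without keep_artifacts; re-run with it enabled."""


def univariate_tests(X: np.ndarray, y: np.ndarray, kinds: list[str]) -> np.ndarray:
    """Two-sided p-value per feature for class association.

    Rank-sum (exact for small untied samples, normal approximation with tie
    correction otherwise) for continuous/count features; Pearson chi-square
    without continuity correction for binary features.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("univariate tests require both classes")
    p_values = np.ones(X.shape[1])
    for j, kind in enumerate(kinds):
        col = X[:, j]
        if np.unique(col).size < 2:
            continue  # single observed level: p = 1 by convention
        a, b = col[y == 1], col[y == 0]
        if kind == KIND_BINARY:
            table = np.array(
                [
                    [(a == 0).sum(), (a == 1).sum()],
                    [(b == 0).sum(), (b == 1).sum()],
                ]
            )
            expected = stats.contingency.expected_freq(table)
            if (expected < 1.0).any():
                logger.debug("chi-square cell with expected count < 1 for feature %d", j)
            p_values[j] = stats.chi2_contingency(table, correction=False)[1]
        else:
            p_values[j] = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
    return p_values


def selection_frequency(result: RunResult, cohort: CohortTable) -> pd.DataFrame:
    """Per feature x ratio: % of training sets retaining the feature."""
    _require_artifacts(result)
    names = cohort.feature_names
    rows = []
    for ratio in result.config.ratios:
        arts = [a for a in result.artifacts if a.ratio == ratio]
        masks = np.concatenate([a.masks for a in arts], axis=0)
        freq = 100.0 * masks.mean(axis=0)
        for name, f in zip(names, freq):
            rows.append({"feature": name, "ratio": ratio, "selection_pct": float(f),
                         "n_training_sets": masks.shape[0]})
    return pd.DataFrame(rows)


def significance_frequency(
    result: RunResult, cohort: CohortTable, max_folds: int | None = None
) -> pd.DataFrame:
    """Per feature x ratio: % of training sets with p < 0.1.

    Tests run on the same (preprocessed) training rows the sub-models saw;
    rank-based and contingency tests are unaffected by standardization.
    ``max_folds`` restricts the pooling to the first folds for speed; the
    denominator is reported alongside.
    """
    _require_artifacts(result)
    if not result.artifacts or not result.artifacts[0].train_sets:
        raise ArtifactsMissingError(
            "training-set indices were not retained; re-run with keep_artifacts=True"
        )
    names = cohort.feature_names
    kinds = [f.kind for f in cohort.schema]
    X, y = cohort.X, cohort.y
    rows = []
    for ratio in result.config.ratios:
        arts = [a for a in result.artifacts if a.ratio == ratio]
        if max_folds is not None:
            arts = [a for a in arts if a.fold < max_folds]
        sig = np.zeros(len(names))
        n_sets = 0
        for art in arts:
            for idx in art.train_sets:
                p = univariate_tests(X[idx], y[idx], kinds)
                sig += p < P_THRESHOLD
                n_sets += 1
        for name, s in zip(names, sig):
            rows.append(
                {
                    "feature": name,
                    "ratio": ratio,
                    "significance_pct": 100.0 * float(s) / n_sets,
                    "n_training_sets": n_sets,
                }
            )
    return pd.DataFrame(rows)


def frequency_table(
    result: RunResult, cohort: CohortTable, max_folds: int | None = None
) -> pd.DataFrame:
    """Joined selection + significance frequencies (feature x ratio)."""
    sel = selection_frequency(result, cohort)
    sig = significance_frequency(result, cohort, max_folds=max_folds)
    return sel.merge(
        sig[["feature", "ratio", "significance_pct"]], on=["feature", "ratio"]
    )


def _require_artifacts(result: RunResult) -> None:
    if not result.artifacts:
        raise ArtifactsMissingError(
            "no artifacts retained on this run; re-run with keep_artifacts=True "
            "(CLI: --keep-artifacts)"
        )
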