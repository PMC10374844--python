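"""ROC/AUC, Youden-index thresholding, confusion metrics, and the
no-resampling baseline.

The ROC curve is built over all candidate cuts (midpoints between adjacent
distinct scores, plus one cut below the minimum and one at the maximum)
with the strict decision rule ``rare iff score > threshold``.  The AUC is
the trapezoidal area of that curve, which equals the Mann-Whitney
concordance statistic P(score_rare > score_abundant) + 0.5 P(equal).

The operating threshold maximizes Youden's J = sensitivity + specificity
- 1; ties resolve to the lower threshold (favoring sensitivity — the
screening-oriented choice).  Reported metrics:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    G-mean      = sqrt(sensitivity * specificity)

The *original model* baseline shares the ML backbone (Gini selection +
linear SVM) but trains one model per leave-one-out fold on all remaining
patients, with no resampling and no voting — the reference against which
the under-sampling ensemble's imbalance handling is judged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .base_model import fit_base_model
from .cohort import CohortTable
from .config import STANDARDIZE_AS_PUBLISHED, RunConfig
from .ensemble import _seed_for
from .preprocess import standardize

logger = logging.getLogger("ovrisk")


@dataclass
class RocCurve:
    """Threshold-indexed operating points plus the trapezoidal AUC."""

    thresholds: np.ndarray  # ascending
    sensitivity: np.ndarray  # non-increasing along thresholds
    specificity: np.ndarray
    auc: float


def roc_curve_points(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """Alias-free name used internally; see :func:`roc_auc`."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("ROC needs both classes present")
    distinct = np.unique(scores)
    cuts = [distinct[0] - 1.0]
    cuts.extend(0.5 * (distinct[:-1] + distinct[1:]))
    cuts.append(distinct[-1])
    cuts = np.asarray(cuts)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    sens = np.array([(scores[pos] > t).sum() / n_pos for t in cuts])
    spec = np.array([(scores[~pos] <= t).sum() / n_neg for t in cuts])
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))  # ties at one FPR form a vertical segment
    auc = float(np.trapezoid(sens[order], fpr[order]))
    return RocCurve(thresholds=cuts, sensitivity=sens, specificity=spec, auc=auc)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve over all candidate cuts and its trapezoidal AUC."""
    return roc_curve_points(scores, labels)


def youden_threshold(roc: RocCurve) -> float:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties resolve to the lowest such threshold.  A degenerate curve
    (constant scores, J = 0 everywhere) is allowed and logged.
    """
    if roc.thresholds.size == 0:
        raise ValueError("empty ROC curve")
    j = roc.sensitivity + roc.specificity - 1.0
    best = float(np.max(j))
    if best <= 0.0:
        logger.warning("degenerate ROC: Youden's J is %.3f at every cut", best)
    idx = int(np.argmax(j))  # argmax returns the first (= lowest threshold)
    return float(roc.thresholds[idx])


@dataclass
class MetricsReport:
    """Confusion-matrix metrics at a fixed threshold, plus the AUC."""

    threshold: float
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    gmean: float
    auc: float

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "gmean": self.gmean,
            "auc": self.auc,
        }


def gmean(sensitivity: float, specificity: float) -> float:
    """Geometric mean of sensitivity and specificity."""
    return float(np.sqrt(sensitivity * specificity))


def confusion_metrics(scores: np.ndarray, labels: np.ndarray, threshold: float) -> MetricsReport:
    """Metrics with the strict rule: predicted rare iff score > threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    pred = scores > threshold
    pos = labels == 1
    tp = int((pred & pos).sum())
    tn = int((~pred & ~pos).sum())
    fp = int((pred & ~pos).sum())
    fn = int((~pred & pos).sum())
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return MetricsReport(
        threshold=float(threshold),
        tp=tp,
        tn=tn,
        fp=fp,
        fn=fn,
        accuracy=(tp + tn) / labels.size,
        sensitivity=sens,
        specificity=spec,
        gmean=gmean(sens, spec),
        auc=roc_auc(scores, labels).auc,
    )


def evaluate_predictions(scores: np.ndarray, labels: np.ndarray) -> MetricsReport:
    """Full evaluation: ROC -> Youden threshold -> confusion metrics.

    As published, the threshold is chosen on the same leave-one-out scores
    being reported (an optimistic convention; see the methods note).
    """
    roc = roc_auc(scores, labels)
    thr = youden_threshold(roc)
    return confusion_metrics(scores, labels, thr)


def original_model_baseline(cohort: CohortTable, config: RunConfig) -> MetricsReport:
    """Leave-one-out baseline with one backbone fit per fold, no resampling.

    Trains on the entire remaining (imbalanced) cohort each fold; the seed
    scheme reuses the fold-level positions of the ensemble's scheme.
    """
    if np.isnan(cohort.X).any():
        raise ValueError("cohort contains missing values; impute first")
    as_published = config.standardize_mode == STANDARDIZE_AS_PUBLISHED
    if as_published:
        table, _ = standardize(cohort)
    else:
        table = cohort
    X, y = table.X, table.y
    n = table.n
    scores = np.empty(n)
    for fold in range(n):
        others = np.arange(n) != fold
        if as_published:
            X_tr, x_te = X[others], X[fold]
        else:
            sub = CohortTable(
                cohort.data.iloc[np.where(others)[0]].reset_index(drop=True), cohort.schema
            )
            sub_std, params = standardize(sub)
            X_tr = sub_std.X
            x_te = standardize(cohort, params)[0].X[fold]
        fit = fit_base_model(
            X_tr,
            y[others],
            seed=_seed_for(config.seed, fold, 0, 0),
            C=config.svm_c,
            tol=config.svm_tol,
            n_trees=config.n_trees,
        )
        scores[fold] = fit.score(x_te)
    return evaluate_predictions(scores, y)
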