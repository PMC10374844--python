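"""The shared ML backbone of every ensemble sub-model.

Each sub-model is a two-stage pipeline fit on one resampled training set:

1. *Feature selection.*  Random-forest Gini importances (100 trees) are
   computed over all features; a feature is retained iff its importance is
   strictly greater than the median importance.  With an even number of
   all-distinct importances this keeps exactly half the features.  If the
   strict rule empties the mask (all importances tied), the model falls
   back to using every feature and logs a warning.

2. *Scoring.*  A soft-margin linear SVM (hinge loss, C = 1) is fit on the
   selected features, and its signed margin is mapped to a [0, 1]
   classification score by Platt calibration (a logistic sigmoid fit on the
   training margins with Platt's smoothed targets, which keeps the fit
   finite even on separable training sets).  Scores above 0.5 mean the
   sub-model votes for the rare class.

The SVM is unweighted: class imbalance is handled upstream by the
under-sampling ensemble, not by per-class weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .forest import gini_importances

logger = logging.getLogger("ovrisk")

#: default SVM hyperparameters (the published setup names none; fixed here)
DEFAULT_C = 1.0
DEFAULT_TOL = 1e-4
DEFAULT_N_TREES = 100


def select_features(
    X: np.ndarray, y: np.ndarray, n_trees: int = DEFAULT_N_TREES, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Gini-importance feature selection with the strict median rule.

    Returns ``(mask, importances)``: importances are non-negative and sum
    to one; ``mask[j]`` is True iff ``importances[j] > median(importances)``,
    falling back to all features when that strict rule selects nothing.
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("feature selection requires both classes in y")
    if X.shape[1] < 2:
        raise ValueError("feature selection requires at least 2 features")
    imp = gini_importances(X, y, n_trees=n_trees, seed=seed)
    mask = imp > np.median(imp)
    if not mask.any():
        logger.warning("all Gini importances tied at the median; keeping all features")
        mask = np.ones_like(mask, dtype=bool)
    return mask, imp


def platt_calibrate(margins: np.ndarray, y: np.ndarray, max_iter: int = 100) -> tuple[float, float]:
    """Fit ``score = sigmoid(a*margin + b)`` by Newton's method.

    Uses Platt's smoothed targets t+ = (N+ + 1)/(N+ + 2), t- = 1/(N- + 2),
    which regularize the fit so the optimum stays finite on perfectly
    separated margins.  Returns ``(a, b)`` with ``a > 0`` whenever higher
    margins associate with the positive class.
    """
    m = np.asarray(margins, dtype=float)
    y = np.asarray(y)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    a, b = 1.0, 0.0
    if np.ptp(m) == 0.0:  # constant margin: only the intercept is identified
        p = t.mean()
        return 0.0, float(np.log(p / (1.0 - p)))
    for _ in range(max_iter):
        z = a * m + b
        p = 1.0 / (1.0 + np.exp(-z))
        g = p - t
        grad = np.array([(g * m).sum(), g.sum()])
        w = np.maximum(p * (1.0 - p), 1e-12)
        h11 = (w * m * m).sum()
        h12 = (w * m).sum()
        h22 = w.sum()
        det = h11 * h22 - h12 * h12
        if det <= 1e-300:
            break
        da = (h22 * grad[0] - h12 * grad[1]) / det
        db = (h11 * grad[1] - h12 * grad[0]) / det
        a -= da
        b -= db
        if abs(da) < 1e-10 and abs(db) < 1e-10:
            break
    return float(a), float(b)


@dataclass
class BaseModelFit:
    """A fitted sub-model: selection mask, linear SVM, calibration.

    The calibrated score is ``sigmoid(calib_a * margin + calib_b)`` where
    ``margin = weights . x[selected] + intercept`` — a strictly monotone
    map of the SVM margin whenever ``calib_a > 0``.  ``train_mean`` stores
    the training-set feature means (full feature order), the background
    needed for exact linear Shapley explanations.
    """

    selected: np.ndarray  # bool mask, full feature order
    importances: np.ndarray
    weights: np.ndarray  # over selected features
    intercept: float
    calib_a: float
    calib_b: float
    seed: int
    train_mean: np.ndarray  # full feature order
    n_train: int = 0

    def margin(self, x: np.ndarray) -> float:
        return float(self.weights @ np.asarray(x, dtype=float)[self.selected] + self.intercept)

    def score(self, x: np.ndarray) -> float:
        return self.score_of_margin(self.margin(x))

    def score_of_margin(self, m: float) -> float:
        return float(1.0 / (1.0 + np.exp(-(self.calib_a * m + self.calib_b))))

    def to_dict(self) -> dict:
        """JSON-ready model card for audit."""
        return {
            "selected": self.selected.astype(int).tolist(),
            "importances": np.round(self.importances, 6).tolist(),
            "weights": np.round(self.weights, 6).tolist(),
            "intercept": round(self.intercept, 6),
            "calibration": [round(self.calib_a, 6), round(self.calib_b, 6)],
            "seed": self.seed,
            "n_train": self.n_train,
        }


def fit_base_model(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    C: float = DEFAULT_C,
    tol: float = DEFAULT_TOL,
    n_trees: int = DEFAULT_N_TREES,
    mask: np.ndarray | None = None,
) -> BaseModelFit:
    """Fit the full backbone (selection + linear SVM + calibration).

    ``mask`` fixes the selected-feature set and skips the forest entirely
    (importances then read as uniform); used when the selection is supplied
    externally, e.g. to audit the SVM stage in isolation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        imp = np.full(X.shape[1], 1.0 / X.shape[1])
    else:
        mask, imp = select_features(X, y, n_trees=n_trees, seed=seed)
    Xs = X[:, mask]
    svm = SVC(C=C, tol=tol, kernel="linear")
    svm.fit(Xs, y)
    w = np.asarray(svm.coef_).ravel().copy()
    b = float(svm.intercept_[0])
    margins = Xs @ w + b
    a, pb = platt_calibrate(margins, y)
    return BaseModelFit(
        selected=mask,
        importances=imp,
        weights=w,
        intercept=b,
        calib_a=a,
        calib_b=pb,
        seed=seed,
        train_mean=X.mean(axis=0),
        n_train=X.shape[0],
    )


def fit_score(
    X_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    seed: int = 0,
    C: float = DEFAULT_C,
    tol: float = DEFAULT_TOL,
    n_trees: int = DEFAULT_N_TREES,
) -> tuple[float, BaseModelFit]:
    """Fit the backbone on a training set and score one held-out patient.

    The score lies in [0, 1]; values above 0.5 predict the rare class.
    Deterministic given identical inputs and seed.
    """
    fit = fit_base_model(X_train, y_train, seed=seed, C=C, tol=tol, n_trees=n_trees)
    x_test = np.asarray(x_test, dtype=float)
    if not np.isfinite(x_test).all():
        raise ValueError("non-finite feature values in test vector")
    return fit.score(x_test), fit
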