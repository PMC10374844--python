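"""ROC/AUC, Youden thresholding, confusion metrics, and the baseline."""

import logging

import numpy as np
import pytest
from scipy import stats

import ovrisk
from ovrisk.config import RunConfig
from ovrisk.evaluate import (
    confusion_metrics,
    evaluate_predictions,
    gmean,
    original_model_baseline,
    roc_auc,
    youden_threshold,
)


def test_auc_concordance_worked_example():
    # rare {0.9, 0.4}, abundant {0.8, 0.1, 0.2}: 5 concordant of 6 pairs,
    # no ties (0.4 < 0.8 is the single discordance)
    scores = np.array([0.9, 0.4, 0.8, 0.1, 0.2])
    labels = np.array([1, 1, 0, 0, 0])
    assert roc_auc(scores, labels).auc == pytest.approx(5 / 6)
    # a tied pair counts half: rare {0.9, 0.4} vs abundant {0.4, 0.1, 0.2}
    scores_tied = np.array([0.9, 0.4, 0.4, 0.1, 0.2])
    assert roc_auc(scores_tied, labels).auc == pytest.approx(5.5 / 6)


def test_perfect_separation_auc_one():
    scores = np.array([0.9, 0.8, 0.2, 0.1])
    labels = np.array([1, 1, 0, 0])
    assert roc_auc(scores, labels).auc == 1.0


def test_single_class_rejected():
    with pytest.raises(ValueError, match="both classes"):
        roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


def test_auc_equals_mann_whitney_concordance():
    """Trapezoidal AUC == rank concordance with half-weight ties (oracle:
    scipy's Mann-Whitney U), on random tied and untied instances."""
    rng = np.random.default_rng(0)
    for trial in range(30):
        n = int(rng.integers(5, 50))
        labels = np.zeros(n, int)
        labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
        if labels.sum() in (0, n):
            continue
        scores = np.round(rng.uniform(size=n), int(rng.integers(1, 3)))  # force ties
        u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        oracle = u / (labels.sum() * (n - labels.sum()))
        assert roc_auc(scores, labels).auc == pytest.approx(oracle, abs=1e-12)


def test_sensitivity_monotone_along_thresholds():
    rng = np.random.default_rng(1)
    scores = rng.uniform(size=40)
    labels = (rng.uniform(size=40) < 0.3).astype(int)
    roc = roc_auc(scores, labels)
    assert (np.diff(roc.sensitivity) <= 1e-12).all()


def _youden_scan_oracle(scores, labels):
    best_j, best_t = -np.inf, None
    for t in np.sort(np.unique(np.r_[scores, scores - 1e-9, scores.min() - 1.0])):
        pred = scores > t
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return best_j


def test_youden_threshold_matches_exhaustive_scan():
    rng = np.random.default_rng(2)
    for _ in range(25):
        n = int(rng.integers(6, 40))
        labels = np.zeros(n, int)
        labels[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] = 1
        if labels.sum() in (0, n):
            continue
        scores = np.round(rng.uniform(size=n), 2)
        roc = roc_auc(scores, labels)
        thr = youden_threshold(roc)
        pred = scores > thr
        sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
        spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
        assert sens + spec - 1 == pytest.approx(_youden_scan_oracle(scores, labels), abs=1e-12)


def test_youden_perfect_separation_midpoint():
    scores = np.array([0.9, 0.8, 0.2, 0.1])
    labels = np.array([1, 1, 0, 0])
    roc = roc_auc(scores, labels)
    thr = youden_threshold(roc)
    assert 0.2 <= thr <= 0.8
    m = confusion_metrics(scores, labels, thr)
    assert m.sensitivity + m.specificity - 1 == 1.0


def test_youden_constant_scores_degenerate(caplog):
    scores = np.full(6, 0.5)
    labels = np.array([1, 0, 0, 1, 0, 0])
    with caplog.at_level(logging.WARNING, logger="ovrisk"):
        thr = youden_threshold(roc_auc(scores, labels))
    assert "degenerate" in caplog.text.lower()
    m = confusion_metrics(scores, labels, thr)
    assert m.sensitivity + m.specificity - 1 == pytest.approx(0.0)


# -- confusion metrics ------------------------------------------------------


def test_hand_counted_confusion_table():
    # TP=2, FN=2, TN=6, FP=2
    scores = np.r_[[0.9, 0.8], [0.2, 0.3], [0.1] * 6, [0.7, 0.95]]
    labels = np.r_[[1, 1], [1, 1], [0] * 6, [0, 0]]
    m = confusion_metrics(scores, labels, threshold=0.5)
    assert (m.tp, m.fn, m.tn, m.fp) == (2, 2, 6, 2)
    assert m.accuracy == pytest.approx(8 / 12)
    assert m.sensitivity == pytest.approx(0.5)
    assert m.specificity == pytest.approx(0.75)
    assert m.gmean == pytest.approx(np.sqrt(0.375))


def test_all_correct_tiny():
    m = confusion_metrics(np.array([0.9, 0.1]), np.array([1, 0]), 0.5)
    assert (m.accuracy, m.sensitivity, m.specificity, m.gmean) == (1, 1, 1, 1)


def test_published_gmean_requires_square_root():
    # 57.1% sensitivity and 85.3% specificity give the published 69.8%
    # only with the square root in the G-mean
    assert round(100 * gmean(0.571, 0.853), 1) == 69.8


def test_gmean_and_accuracy_identities():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n = int(rng.integers(8, 60))
        labels = (rng.uniform(size=n) < 0.3).astype(int)
        if labels.sum() in (0, n):
            continue
        scores = rng.uniform(size=n)
        m = confusion_metrics(scores, labels, float(rng.uniform()))
        assert m.tp + m.tn + m.fp + m.fn == n
        assert m.gmean**2 == pytest.approx(m.sensitivity * m.specificity, abs=1e-12)
        p, q = labels.sum(), n - labels.sum()
        assert m.accuracy == pytest.approx((m.sensitivity * p + m.specificity * q) / n)


def test_threshold_rule_is_strictly_greater():
    scores = np.array([0.5, 0.5, 0.7, 0.3])
    labels = np.array([1, 0, 1, 0])
    m = confusion_metrics(scores, labels, threshold=0.5)
    assert m.tp == 1 and m.fn == 1  # the score==threshold rare case is negative


# -- the no-resampling baseline --------------------------------------------


def test_baseline_matches_ensemble_on_balanced_separable_data():
    # near-balanced (11/13) so the abundant pool still covers ratio 1:1
    cfg_gen = ovrisk.scaled_config(24, 11, seed=4, effects={"ca125": 6.0}, with_missingness=False)
    cohort = ovrisk.generate_cohort(cfg_gen)
    # balanced classes leave no abundant surplus, so only ratio 1:1 applies
    cfg = RunConfig(seed=0, n_models=3, n_trees=25, ratios=(1,))
    base = original_model_baseline(cohort, cfg)
    ens = evaluate_predictions(ovrisk.loo_predict(cohort, cfg).scores, cohort.y)
    assert base.auc > 0.95
    assert ens.auc > 0.95


def test_baseline_below_ensemble_under_imbalance_with_signal():
    """Paired-seed comparison at a scaled-down size: with moderate planted
    signal and strong imbalance, under-sampling should beat training on
    the raw imbalanced data in most replicates."""
    wins = 0
    n_seeds = 10
    for seed in range(n_seeds):
        gen = ovrisk.scaled_config(60, 8, seed=100 + seed, effects={"ca125": 1.0})
        cohort, _ = ovrisk.impute_missing(ovrisk.generate_cohort(gen))
        cfg = RunConfig(seed=seed, n_models=10, n_trees=10)
        ens_auc = roc_auc(ovrisk.loo_predict(cohort, cfg).scores, cohort.y).auc
        base_auc = original_model_baseline(cohort, cfg).auc
        wins += ens_auc > base_auc
    assert wins > n_seeds / 2
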