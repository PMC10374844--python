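"""Leave-one-out under-sampling ensemble: resampling plans, majority and
soft voting, and the full prediction loop.

For every held-out patient, ``n_models`` (default 100) sub-models are fit
per class ratio 1:r (r in {1, 2, 3}).  Each training set contains *all*
available rare-class patients (all 14 when the held-out patient is
abundant; the remaining 13 when they are rare) plus ``r * n_rare``
abundant-class patients drawn uniformly without replacement, independently
across sub-models — so at defaults 300 sub-models are fit per fold.

Per ratio, the sub-models' class votes are combined by majority voting
(50/50 ties resolve to the rare class — the screening-oriented choice —
and are logged).  The ratio's aggregated score is the *maximum* score
among the sub-models that voted rare when the majority class is rare, and
the *minimum* score among those that voted abundant when the majority
class is abundant.  The three ratio scores are then soft-voted (arithmetic
mean) into the final ensemble score.

Seed scheme: every random draw is derived positionally from the master
seed via ``numpy.random.SeedSequence(master, spawn_key=(fold, ratio, k))``
with k = 0 for the resampling plan and k = model_index + 1 for each
sub-model fit.  Any single sub-model is therefore re-derivable in
isolation, and folds are independent (results are identical however the
folds are scheduled).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .base_model import BaseModelFit, fit_base_model
from .cohort import CohortTable
from .config import STANDARDIZE_AS_PUBLISHED, RunConfig
from .preprocess import standardize

logger = logging.getLogger("ovrisk")

RARE, ABUNDANT = 1, 0


class ResamplingError(ValueError):
    """Abundant pool too small for the requested ratio."""


def _seed_for(master: int, *key: int) -> int:
    """Position-derived 31-bit seed from the master seed."""
    ss = np.random.SeedSequence(master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class ResamplingPlan:
    """Training-set index sets for one ratio (indices into the donor pool)."""

    ratio: int
    n_models: int
    rare_idx: np.ndarray  # shared by every sub-model
    abundant_sets: list[np.ndarray]  # one per sub-model, len == n_models

    def training_sets(self) -> list[np.ndarray]:
        return [np.concatenate([self.rare_idx, a]) for a in self.abundant_sets]


def make_training_sets(
    others: CohortTable | np.ndarray, ratio: int, n_models: int, seed: int
) -> ResamplingPlan:
    """Build ``n_models`` under-sampled 1:ratio training index sets.

    ``others`` is the cohort with the held-out patient removed (or just its
    outcome vector); returned indices are positions within it.  Every set
    holds all rare samples plus ``ratio * n_rare`` abundant samples drawn
    without replacement, independently across sets.
    """
    y = others.y if isinstance(others, CohortTable) else np.asarray(others, dtype=int)
    rng = np.random.default_rng(seed)
    return _sample_plan(y, ratio, n_models, rng)


def _sample_plan(
    y: np.ndarray, ratio: int, n_models: int, rng: np.random.Generator
) -> ResamplingPlan:
    rare_idx = np.where(y == RARE)[0]
    abundant_idx = np.where(y == ABUNDANT)[0]
    need = ratio * rare_idx.size
    if abundant_idx.size < need:
        raise ResamplingError(
            f"ratio 1:{ratio} needs {need} abundant samples, pool has {abundant_idx.size}"
        )
    if abundant_idx.size == need:
        logger.warning(
            "abundant pool exactly matches ratio 1:%d demand; all %d training sets identical",
            ratio, n_models,
        )
    sets = [rng.choice(abundant_idx, size=need, replace=False) for _ in range(n_models)]
    return ResamplingPlan(ratio=ratio, n_models=n_models, rare_idx=rare_idx, abundant_sets=sets)


@dataclass
class RatioVote:
    """Majority-vote outcome of one ratio's sub-models for one patient."""

    ratio: int
    winning_class: int
    score: float
    votes: list[tuple[int, float]]  # per sub-model (class, score)
    selected_model: int  # index of the sub-model whose score was propagated
    tie: bool = False


def majority_vote(votes: list[tuple[int, float]], ratio: int = 0) -> RatioVote:
    """Combine per-sub-model (class, score) pairs for one ratio.

    Winning class is the modal class (50/50 tie -> rare, logged).  The
    aggregated score is max over rare-voting sub-models' scores if the
    winner is rare, else min over abundant-voting sub-models' scores; the
    index of the score-supplying sub-model is recorded for explanation.
    """
    if not votes:
        raise ValueError("empty vote list")
    classes = np.array([c for c, _ in votes])
    scores = np.array([s for _, s in votes])
    if scores.min() < 0.0 or scores.max() > 1.0:
        raise ValueError("scores must lie in [0, 1]")
    n_rare = int((classes == RARE).sum())
    n_abun = classes.size - n_rare
    tie = n_rare == n_abun
    if tie:
        logger.info("50/50 majority-vote tie (%d votes); resolved to rare class", classes.size)
    winner = RARE if n_rare >= n_abun else ABUNDANT
    agree = np.where(classes == winner)[0]
    if winner == RARE:
        sel = agree[int(np.argmax(scores[agree]))]
    else:
        sel = agree[int(np.argmin(scores[agree]))]
    return RatioVote(
        ratio=ratio,
        winning_class=winner,
        score=float(scores[sel]),
        votes=list(votes),
        selected_model=int(sel),
        tie=tie,
    )


def soft_vote(ratio_scores) -> float:
    """Arithmetic mean of the per-ratio aggregated scores."""
    scores = np.asarray(list(ratio_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("no ratio scores to combine")
    if scores.min() < 0.0 or scores.max() > 1.0:
        raise ValueError("scores must lie in [0, 1]")
    return float(scores.mean())


@dataclass
class EnsemblePrediction:
    """All voting stages for one held-out patient."""

    patient_id: str
    true_label: int
    ratio_votes: dict[int, RatioVote]
    final_score: float
    final_class: int | None = None  # set once an evaluation threshold exists


@dataclass
class FoldRatioArtifacts:
    """Retained per-sub-model state for one (fold, ratio) pair."""

    fold: int
    ratio: int
    masks: np.ndarray  # (n_models, n_features) bool
    train_sets: list[np.ndarray]  # absolute cohort row indices
    fits: list[BaseModelFit]


@dataclass
class RunResult:
    """Output bundle of :func:`loo_predict`."""

    predictions: list[EnsemblePrediction]
    config: RunConfig
    artifacts: list[FoldRatioArtifacts] = field(default_factory=list)
    n_vote_ties: int = 0

    @property
    def scores(self) -> np.ndarray:
        return np.array([p.final_score for p in self.predictions])

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.true_label for p in self.predictions])


def _check_ready(cohort: CohortTable) -> None:
    n_abun, n_rare = cohort.class_counts()
    if n_rare < 2 or n_abun < 2:
        raise ValueError("need at least 2 patients per class for leave-one-out")
    if np.isnan(cohort.X).any():
        raise ValueError("cohort contains missing values; impute first")


def _fold_views(cohort: CohortTable, config: RunConfig, fold: int, X_all: np.ndarray):
    """Training pool / test vector for one fold under the configured
    standardization mode (``X_all`` is the pre-standardized matrix in
    as-published mode, the raw matrix otherwise)."""
    n = cohort.n
    others = np.arange(n) != fold
    others_rows = np.where(others)[0]
    if config.standardize_mode == STANDARDIZE_AS_PUBLISHED:
        return others_rows, X_all[others], X_all[fold]
    sub = CohortTable(cohort.data.iloc[others_rows].reset_index(drop=True), cohort.schema)
    sub_std, params = standardize(sub)
    x_test = standardize(cohort, params)[0].X[fold]
    return others_rows, sub_std.X, x_test


def predict_fold(
    cohort: CohortTable,
    config: RunConfig,
    fold: int,
    X_all: np.ndarray | None = None,
    y_all: np.ndarray | None = None,
    keep_artifacts: bool | None = None,
) -> tuple[EnsemblePrediction, list[FoldRatioArtifacts]]:
    """Predict one held-out patient (by row position) with the ensemble.

    Used by :func:`loo_predict` for every fold in turn, and standalone when
    only one patient's prediction/explanation is wanted.  Seeds depend only
    on (config.seed, fold, ratio, model), never on which folds ran before.
    """
    if X_all is None or y_all is None:
        _check_ready(cohort)
        if config.standardize_mode == STANDARDIZE_AS_PUBLISHED:
            table, _ = standardize(cohort)
            X_all, y_all = table.X, table.y
        else:
            X_all, y_all = cohort.X, cohort.y
    keep = config.keep_artifacts if keep_artifacts is None else keep_artifacts
    others_rows, X_tr_pool, x_test = _fold_views(cohort, config, fold, X_all)
    y_pool = y_all[others_rows]

    ratio_votes: dict[int, RatioVote] = {}
    artifacts: list[FoldRatioArtifacts] = []
    for ratio in config.ratios:
        plan_rng = np.random.default_rng(_seed_for(config.seed, fold, ratio, 0))
        plan = _sample_plan(y_pool, ratio, config.n_models, plan_rng)
        votes: list[tuple[int, float]] = []
        fits: list[BaseModelFit] = []
        masks = np.empty((config.n_models, X_all.shape[1]), dtype=bool)
        train_sets: list[np.ndarray] = []
        for m, train_idx in enumerate(plan.training_sets()):
            abs_idx = others_rows[train_idx]
            assert fold not in abs_idx, "held-out patient leaked into training"
            model_seed = _seed_for(config.seed, fold, ratio, m + 1)
            fit = fit_base_model(
                X_tr_pool[train_idx],
                y_pool[train_idx],
                seed=model_seed,
                C=config.svm_c,
                tol=config.svm_tol,
                n_trees=config.n_trees,
            )
            s = fit.score(x_test)
            votes.append((RARE if s > 0.5 else ABUNDANT, s))
            masks[m] = fit.selected
            if keep:
                fits.append(fit)
                train_sets.append(abs_idx)
        vote = majority_vote(votes, ratio=ratio)
        ratio_votes[ratio] = vote
        if keep:
            artifacts.append(
                FoldRatioArtifacts(
                    fold=fold, ratio=ratio, masks=masks, train_sets=train_sets, fits=fits
                )
            )
    prediction = EnsemblePrediction(
        patient_id=cohort.patient_ids[fold],
        true_label=int(y_all[fold]),
        ratio_votes=ratio_votes,
        final_score=soft_vote([v.score for v in ratio_votes.values()]),
    )
    return prediction, artifacts


def loo_predict(cohort: CohortTable, config: RunConfig) -> RunResult:
    """Leave-one-out prediction with the full resampled ensemble.

    ``cohort`` must be complete (imputed).  In the default "as-published"
    standardization mode continuous features are scaled once on the whole
    cohort before the loop; in "train-only" mode scaling parameters are
    re-estimated on each fold's remaining patients and applied to the
    held-out one.  Deterministic given ``config.seed``; folds are
    independent, so any execution order yields identical results.
    """
    _check_ready(cohort)
    if config.standardize_mode == STANDARDIZE_AS_PUBLISHED:
        table, _ = standardize(cohort)
        X_all, y_all = table.X, table.y
    else:
        X_all, y_all = cohort.X, cohort.y

    predictions: list[EnsemblePrediction] = []
    artifacts: list[FoldRatioArtifacts] = []
    n_ties = 0
    for fold in range(cohort.n):
        pred, arts = predict_fold(cohort, config, fold, X_all=X_all, y_all=y_all)
        predictions.append(pred)
        artifacts.extend(arts)
        n_ties += sum(v.tie for v in pred.ratio_votes.values())
        if fold % 50 == 49:
            logger.info("leave-one-out progress: %d/%d folds", fold + 1, cohort.n)
    logger.info("leave-one-out complete: %d folds, %d vote ties", cohort.n, n_ties)
    return RunResult(predictions=predictions, config=config, artifacts=artifacts, n_vote_ties=n_ties)
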