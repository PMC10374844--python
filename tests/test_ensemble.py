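"""Resampling plans, majority/soft voting, and the leave-one-out loop."""

import logging
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ovrisk
from ovrisk.config import RunConfig
from ovrisk.ensemble import (
    ResamplingError,
    loo_predict,
    majority_vote,
    make_training_sets,
    predict_fold,
    soft_vote,
)


@pytest.fixture(scope="module")
def small_complete_cohort():
    cfg = ovrisk.scaled_config(40, 6, seed=11, effects={"ca125": 1.5})
    table = ovrisk.generate_cohort(cfg)
    complete, _ = ovrisk.impute_missing(table)
    return complete


# -- resampling plans -------------------------------------------------------


def test_training_set_sizes_follow_ratio(default_cohort):
    # 14 rare + ratio*14 abundant; e.g. ratio 3 -> 56 rows
    plan = make_training_sets(default_cohort, ratio=3, n_models=5, seed=0)
    for ts in plan.training_sets():
        assert ts.size == 14 + 42
    assert plan.rare_idx.size == 14


@pytest.mark.parametrize("ratio", [1, 2, 3])
def test_exact_class_ratio_within_each_set(default_cohort, ratio):
    plan = make_training_sets(default_cohort, ratio=ratio, n_models=4, seed=1)
    y = default_cohort.y
    for ts in plan.training_sets():
        counts = Counter(y[ts])
        assert counts[1] * ratio == counts[0]


def test_abundant_draws_without_replacement_and_varying(default_cohort):
    plan = make_training_sets(default_cohort, ratio=2, n_models=10, seed=3)
    sets = [frozenset(a.tolist()) for a in plan.abundant_sets]
    assert all(len(s) == 28 for s in sets)  # no within-set duplicates
    assert len(set(sets)) > 1  # draws differ across models


def test_pool_too_small_names_ratio():
    y = np.r_[np.ones(5, int), np.zeros(9, int)]
    with pytest.raises(ResamplingError, match="1:2"):
        make_training_sets(y, ratio=2, n_models=3, seed=0)


def test_forced_identical_sets_warn(caplog):
    y = np.r_[np.ones(5, int), np.zeros(5, int)]
    with caplog.at_level(logging.WARNING, logger="ovrisk"):
        plan = make_training_sets(y, ratio=1, n_models=3, seed=0)
    assert "identical" in caplog.text
    sets = {frozenset(a.tolist()) for a in plan.abundant_sets}
    assert len(sets) == 1


def test_same_seed_same_plan(default_cohort):
    p1 = make_training_sets(default_cohort, ratio=2, n_models=6, seed=42)
    p2 = make_training_sets(default_cohort, ratio=2, n_models=6, seed=42)
    for a, b in zip(p1.abundant_sets, p2.abundant_sets):
        np.testing.assert_array_equal(a, b)


# -- majority voting --------------------------------------------------------


def test_majority_vote_worked_examples():
    v = majority_vote([(1, 0.9), (1, 0.6), (0, 0.2)])
    assert (v.winning_class, v.score) == (1, 0.9)
    v = majority_vote([(0, 0.4), (0, 0.1), (1, 0.8)])
    assert (v.winning_class, v.score) == (0, 0.1)
    v = majority_vote([(1, 0.7)] * 100)
    assert (v.winning_class, v.score) == (1, 0.7)


def test_fifty_fifty_tie_resolves_rare():
    v = majority_vote([(1, 0.6), (0, 0.4)])
    assert v.winning_class == 1
    assert v.tie


def test_empty_votes_rejected():
    with pytest.raises(ValueError, match="empty"):
        majority_vote([])


def _brute_force_vote(votes):
    """Independent restatement of the published aggregation rule."""
    counts = Counter(c for c, _ in votes)
    winner = 1 if counts[1] >= counts[0] else 0
    pool = [s for c, s in votes if c == winner]
    return winner, (max(pool) if winner == 1 else min(pool))


@given(
    st.lists(
        st.tuples(st.integers(0, 1), st.floats(0, 1, allow_nan=False)),
        min_size=1,
        max_size=25,
    )
)
@settings(max_examples=200, derandomize=True)
def test_majority_vote_matches_brute_force(votes):
    v = majority_vote(votes)
    winner, score = _brute_force_vote(votes)
    assert v.winning_class == winner
    assert v.score == score
    assert votes[v.selected_model] == (v.winning_class, v.score)


def test_raising_selected_score_never_lowers_rare_vote():
    votes = [(1, 0.9), (1, 0.6), (0, 0.2)]
    base = majority_vote(votes).score
    votes[0] = (1, 0.95)
    assert majority_vote(votes).score >= base


# -- soft voting ------------------------------------------------------------


def test_soft_vote_published_examples():
    assert soft_vote([0.62, 0.63, 0.70]) == pytest.approx(0.65)
    assert round(soft_vote([0.15, 0.19, 0.24]), 2) == 0.19


def test_soft_vote_idempotent_and_order_invariant():
    assert soft_vote([0.4, 0.4, 0.4]) == pytest.approx(0.4)
    assert soft_vote([0.1, 0.5, 0.9]) == soft_vote([0.9, 0.1, 0.5])


def test_soft_vote_rejects_out_of_range():
    with pytest.raises(ValueError):
        soft_vote([0.5, 1.2, 0.1])


# -- leave-one-out loop -----------------------------------------------------


def test_loo_structure_and_bounds(small_complete_cohort):
    cfg = RunConfig(seed=5, n_models=4, n_trees=10, keep_artifacts=True)
    res = loo_predict(small_complete_cohort, cfg)
    assert len(res.predictions) == small_complete_cohort.n
    for p in res.predictions:
        assert set(p.ratio_votes) == {1, 2, 3}
        scores = [v.score for v in p.ratio_votes.values()]
        assert min(scores) - 1e-12 <= p.final_score <= max(scores) + 1e-12
        assert p.final_score == pytest.approx(np.mean(scores))
        for v in p.ratio_votes.values():
            assert len(v.votes) == cfg.n_models


def test_loo_training_sets_exclude_held_out_and_keep_ratio(small_complete_cohort):
    cfg = RunConfig(seed=5, n_models=3, n_trees=10, keep_artifacts=True)
    res = loo_predict(small_complete_cohort, cfg)
    y = small_complete_cohort.y
    for art in res.artifacts:
        for ts in art.train_sets:
            assert art.fold not in ts
            counts = Counter(y[ts])
            assert counts[0] == art.ratio * counts[1]


def test_loo_deterministic(small_complete_cohort):
    cfg = RunConfig(seed=8, n_models=2, n_trees=10)
    r1 = loo_predict(small_complete_cohort, cfg)
    r2 = loo_predict(small_complete_cohort, cfg)
    np.testing.assert_array_equal(r1.scores, r2.scores)


def test_predict_fold_matches_loo(small_complete_cohort):
    cfg = RunConfig(seed=8, n_models=2, n_trees=10)
    res = loo_predict(small_complete_cohort, cfg)
    pred, _ = predict_fold(small_complete_cohort, cfg, fold=7)
    assert pred.final_score == res.predictions[7].final_score


def test_single_model_per_ratio_degenerates(small_complete_cohort):
    cfg = RunConfig(seed=2, n_models=1, n_trees=10)
    res = loo_predict(small_complete_cohort, cfg)
    p = res.predictions[0]
    for v in p.ratio_votes.values():
        assert len(v.votes) == 1
        assert v.score == v.votes[0][1]
    assert p.final_score == pytest.approx(np.mean([v.score for v in p.ratio_votes.values()]))


def test_missing_values_rejected():
    t = ovrisk.generate_cohort(ovrisk.default_config(seed=0))
    with pytest.raises(ValueError, match="impute"):
        loo_predict(t, RunConfig(seed=0, n_models=1))
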