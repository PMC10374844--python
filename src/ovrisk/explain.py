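"""Additive per-patient explanations (Shapley values for linear models).

For a linear model f(x) = w.x + b under feature independence, the Shapley
value of feature i at point x with background B is exactly
``w_i * (x_i - mean(B_i))`` — the closed form to which kernel-based
estimators converge.  Because the model is linear, the *base value* (the
expected prediction when no feature is known, i.e. the average prediction
over the training set) equals the margin at the training-set mean, so
additivity ``base + sum(contributions) = margin(x)`` is exact in margin
space.

The reported [0, 1] classification score passes the margin through the
(nonlinear) Platt sigmoid, so margin-space contributions are rescaled by
the secant slope of the calibration map between the base margin and the
evaluation margin.  This keeps additivity exact in score space — the
scale the published force plots use — while preserving each feature's
sign and relative weight; margin-space values are carried alongside for
audit.  Features outside the sub-model's selection mask contribute
exactly zero.

Per ratio, the explained sub-model is the one whose score the majority
vote propagated (the max-scoring rare voter or min-scoring abundant
voter), so the explained score equals the ratio's aggregated score.  The
ensemble explanation averages the three ratio explanations feature-wise —
mirroring soft voting — so a feature pushing in opposite directions under
different ratios nets out near zero.  Averaging over all sub-models of a
ratio instead is available behind a flag.
"""

from __future__ import annotations

import numpy as np

from dataclasses import dataclass, field

from .base_model import BaseModelFit
from .ensemble import RARE, RatioVote


@dataclass
class Explanation:
    """Base value + signed per-feature contributions summing to the score."""

    patient_id: str
    level: str  # "ratio1" | "ratio2" | "ratio3" | "ensemble"
    base_value: float
    contributions: np.ndarray  # score space, full feature order
    score: float
    margin_contributions: np.ndarray | None = None
    feature_names: list[str] = field(default_factory=list)

    def additivity_gap(self) -> float:
        return abs(self.base_value + float(self.contributions.sum()) - self.score)

    def top_features(self, k: int = 8) -> list[tuple[str, float]]:
        """The k features with largest |contribution|, signed."""
        order = np.argsort(-np.abs(self.contributions))[:k]
        names = self.feature_names or [f"x{i}" for i in range(self.contributions.size)]
        return [(names[i], float(self.contributions[i])) for i in order]


def linear_shap(
    fit: BaseModelFit,
    x: np.ndarray,
    background: np.ndarray | None = None,
    patient_id: str = "",
    level: str = "",
    feature_names: list[str] | None = None,
) -> Explanation:
    """Exact Shapley explanation of one sub-model's score at ``x``.

    ``background`` is the training feature matrix (rows x full feature
    order); when omitted, the training means stored on the fit are used —
    for a linear model only the mean matters.  Positive contributions push
    toward the rare class.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] != fit.selected.shape[0]:
        raise ValueError(
            f"feature vector length {x.shape[0]} != schema length {fit.selected.shape[0]}"
        )
    mu = fit.train_mean if background is None else np.asarray(background, dtype=float).mean(axis=0)
    if mu.shape[0] != fit.selected.shape[0]:
        raise ValueError("background feature dimension mismatch")

    phi_margin = np.zeros_like(x)
    phi_margin[fit.selected] = fit.weights * (x[fit.selected] - mu[fit.selected])

    base_margin = fit.margin(mu)  # == mean training margin, by linearity
    margin = fit.margin(x)
    base_value = fit.score_of_margin(base_margin)
    score = fit.score_of_margin(margin)
    # secant slope of the calibration map: exact score-space additivity
    if abs(margin - base_margin) > 1e-300:
        slope = (score - base_value) / (margin - base_margin)
    else:
        slope = 0.0
    return Explanation(
        patient_id=patient_id,
        level=level,
        base_value=base_value,
        contributions=phi_margin * slope,
        score=score,
        margin_contributions=phi_margin,
        feature_names=list(feature_names or []),
    )


def explain_ratio(
    vote: RatioVote,
    fits: list[BaseModelFit],
    x: np.ndarray,
    patient_id: str = "",
    feature_names: list[str] | None = None,
    average_all: bool = False,
) -> Explanation:
    """Explain one ratio's aggregated prediction.

    By default explains the vote-selected sub-model (the only one whose
    score survives aggregation), so ``explanation.score`` equals
    ``vote.score`` exactly.  With ``average_all=True`` the explanations of
    all sub-models are averaged instead (not score-consistent with the
    vote rule; exposed for sensitivity analysis).
    """
    level = f"ratio{vote.ratio}"
    if not average_all:
        exp = linear_shap(
            fits[vote.selected_model], x,
            patient_id=patient_id, level=level, feature_names=feature_names,
        )
        return exp
    parts = [
        linear_shap(f, x, patient_id=patient_id, level=level, feature_names=feature_names)
        for f in fits
    ]
    return _average(parts, level=level)


def explain_ensemble(ratio_explanations: list[Explanation]) -> Explanation:
    """Average the per-ratio explanations into the ensemble explanation.

    Feature-wise mean of contributions; base value and score are the means
    of the per-ratio base values and scores (consistent with soft voting),
    so additivity carries over by linearity.
    """
    if not ratio_explanations:
        raise ValueError("no ratio explanations to combine")
    return _average(ratio_explanations, level="ensemble")


def _average(parts: list[Explanation], level: str) -> Explanation:
    n_feat = max(p.contributions.size for p in parts)

    def pad(v: np.ndarray) -> np.ndarray:
        if v.size == n_feat:
            return v
        out = np.zeros(n_feat)
        out[: v.size] = v  # absent features contribute zero
        return out

    contrib = np.mean([pad(p.contributions) for p in parts], axis=0)
    margin = np.mean([pad(p.margin_contributions) for p in parts], axis=0)
    names = next((p.feature_names for p in parts if p.feature_names), [])
    return Explanation(
        patient_id=parts[0].patient_id,
        level=level,
        base_value=float(np.mean([p.base_value for p in parts])),
        contributions=contrib,
        score=float(np.mean([p.score for p in parts])),
        margin_contributions=margin,
        feature_names=list(names),
    )


def render_force_text(explanation: Explanation, k: int = 8) -> str:
    """Plain-text force layout: top-k features by |contribution|."""
    lines = [
        f"patient {explanation.patient_id} [{explanation.level}]  "
        f"score={explanation.score:.3f}  base={explanation.base_value:.3f}"
    ]
    for name, c in explanation.top_features(k):
        bar = "+" if c >= 0 else "-"
        lines.append(f"  {bar} {name:<16s} {c:+.4f}")
    return "\n".join(lines)
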