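"""Missing-value imputation by nearest fully-observed donor, and
standardization of continuous features.

Imputation follows a proximity rule: for each patient with missing values,
find the single fully-observed patient whose feature vector — restricted to
exactly the features the recipient has observed — minimizes the Euclidean
distance to the recipient, and copy that donor's values into every missing
slot.  Distances are computed on raw (unstandardized) values, since
imputation precedes standardization in the pipeline; binary and count
features enter the distance as-is (0/1 and small integers), which means
large-scale features such as CA-125 dominate the metric.  Equidistant
donors are broken deterministically toward the smaller row index.

Standardization removes the mean and scales to unit (population) variance,
continuous features only; binary and count features pass through untouched.
By default the pipeline standardizes once on the entire cohort before
cross-validation ("as-published" mode); a leakage-safe train-only mode
computes parameters on each training fold instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cohort import KIND_CONTINUOUS, CohortTable

logger = logging.getLogger("ovrisk")


class ImputationError(ValueError):
    """No fully-observed donor exists; relax or pre-fill before imputing."""


@dataclass(frozen=True)
class ImputationRecord:
    """One imputed cell: who received what from whom, and how far away."""

    recipient_id: str
    feature: str
    donor_id: str
    distance: float
    tied: bool = False  # another donor sat at exactly the same distance


def impute_missing(table: CohortTable) -> tuple[CohortTable, list[ImputationRecord]]:
    """Fill every missing value from the nearest fully-observed patient.

    Returns the completed table and one record per imputed cell.  Imputed
    values always come from the observed support (they are copies of donor
    values, never synthesized numbers), so running the imputation twice is
    a no-op.
    """
    X = table.X
    ids = table.patient_ids
    missing = np.isnan(X)
    donor_mask = ~missing.any(axis=1)
    recipients = np.where(missing.any(axis=1))[0]
    if recipients.size == 0:
        return table, []
    if not donor_mask.any():
        raise ImputationError(
            "no patient is fully observed; relax the donor requirement or "
            "pre-fill at least one patient before imputing"
        )
    donor_rows = np.where(donor_mask)[0]
    donors = X[donor_rows]

    X_new = X.copy()
    records: list[ImputationRecord] = []
    names = table.feature_names
    for r in recipients:
        obs = ~missing[r]
        diff = donors[:, obs] - X[r, obs]
        dist = np.sqrt((diff * diff).sum(axis=1))
        best = int(np.argmin(dist))  # ties -> smallest donor row index
        tied = bool((np.abs(dist - dist[best]) < 1e-12).sum() > 1)
        if tied:
            logger.info("imputation tie for patient %s; kept donor %s",
                        ids[r], ids[donor_rows[best]])
        donor_row = donor_rows[best]
        for j in np.where(missing[r])[0]:
            X_new[r, j] = X[donor_row, j]
            records.append(
                ImputationRecord(
                    recipient_id=ids[r],
                    feature=names[j],
                    donor_id=ids[donor_row],
                    distance=float(dist[best]),
                    tied=tied,
                )
            )
    return table.with_X(X_new), records


@dataclass
class StandardizationParams:
    """Per-feature scaling parameters (continuous features only)."""

    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)


def standardize(
    table: CohortTable, params: StandardizationParams | None = None
) -> tuple[CohortTable, StandardizationParams]:
    """Scale continuous features to zero mean and unit variance.

    When ``params`` is given (train-only mode) they are applied as-is;
    otherwise they are estimated from ``table`` (population variance,
    ddof=0).  Raises on a zero-variance continuous feature, naming it.
    """
    X = table.X
    if np.isnan(X).any():
        raise ValueError("standardize requires a complete table (impute first)")
    fit = params is None
    if fit:
        params = StandardizationParams()
    X_new = X.copy()
    for j, f in enumerate(table.schema):
        if f.kind != KIND_CONTINUOUS:
            continue
        if fit:
            mean = float(X[:, j].mean())
            sd = float(X[:, j].std(ddof=0))
            if sd <= 0.0:
                raise ValueError(f"zero-variance continuous feature {f.name!r}")
            params.means[f.name] = mean
            params.sds[f.name] = sd
        mean, sd = params.means[f.name], params.sds[f.name]
        X_new[:, j] = (X[:, j] - mean) / sd
    return table.with_X(X_new), params


def unstandardize(table: CohortTable, params: StandardizationParams) -> CohortTable:
    """Invert :func:`standardize` given its parameters."""
    X = table.X.copy()
    for j, f in enumerate(table.schema):
        if f.kind == KIND_CONTINUOUS:
            X[:, j] = X[:, j] * params.sds[f.name] + params.means[f.name]
    return table.with_X(X)
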