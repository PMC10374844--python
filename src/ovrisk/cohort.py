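"""Patient cohort container, CSV I/O, and clinical-style marginal summaries.

A cohort is a patient-by-feature table of mixed clinical variables
(continuous, binary, count) with a binary outcome: 1 marks the *rare class*
(adnexal tumor found at risk-reducing salpingo-oophorectomy), 0 the
*abundant class* (controls).  Missing feature values are allowed and are
represented as NaN; the outcome is never missing.

The on-disk format is plain UTF-8 CSV with a header row and one patient per
row: ``patient_id``, the 20 schema feature columns in schema order,
``outcome``, and an optional ``subtype`` column (``STIC``/``invasive``/
``none``).  Missing values are written as empty cells and read back from
empty cells or a literal, case-insensitive ``NA`` — nothing else, so typos
fail loudly instead of becoming silent missingness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

KIND_CONTINUOUS = "continuous"
KIND_BINARY = "binary"
KIND_COUNT = "count"
_KINDS = (KIND_CONTINUOUS, KIND_BINARY, KIND_COUNT)

#: subtype labels for rare-class patients
SUBTYPES = ("STIC", "invasive", "none")

#: decimal places kept when writing continuous values
_WRITE_DECIMALS = 6


class SchemaError(ValueError):
    """Column set or schema definition does not match expectations."""


class CohortValidationError(ValueError):
    """A cell value violates its feature kind (with row/column context)."""


@dataclass(frozen=True)
class FeatureSchema:
    """One clinical variable: identifier, printable label, kind and unit.

    ``kind`` drives everything downstream: which marginal sampler the
    synthetic generator uses, whether the preprocessor standardizes the
    column, and which univariate test (rank-sum vs chi-square) applies.
    """

    name: str
    display_name: str
    kind: str
    unit: str = ""
    # generator parameters (populated from the packaged schema file)
    quartiles: tuple[float, float, float] | None = None  # (q1, median, q3)
    lower_bound: float | None = None
    p_yes: float | None = None
    probs: tuple[float, ...] | None = None
    na_count: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise SchemaError(f"unknown feature kind {self.kind!r} for {self.name!r}")


def default_schema() -> list[FeatureSchema]:
    """Load the packaged 20-feature clinical schema (reference-cohort marginals)."""
    text = resources.files("ovrisk.data").joinpath("default_schema.yaml").read_text()
    raw = yaml.safe_load(text)
    out = []
    for entry in raw["features"]:
        p_yes = None
        if entry["kind"] == KIND_BINARY:
            p_yes = entry["yes_count"] / entry["observed"]
        out.append(
            FeatureSchema(
                name=entry["name"],
                display_name=entry["display_name"],
                kind=entry["kind"],
                unit=entry.get("unit", ""),
                quartiles=tuple(entry["quartiles"]) if "quartiles" in entry else None,
                lower_bound=entry.get("lower_bound"),
                p_yes=p_yes,
                probs=tuple(entry["probs"]) if "probs" in entry else None,
                na_count=int(entry.get("na_count", 0)),
            )
        )
    names = [f.name for f in out]
    if len(set(names)) != len(names):
        raise SchemaError("duplicate feature names in schema")
    return out


@dataclass
class CohortTable:
    """Validated patient table: features (NaN = missing), outcome, subtype.

    ``data`` holds one row per patient with columns ``patient_id`` (str),
    one float column per schema feature, ``outcome`` (int 0/1) and
    ``subtype`` (str).  Row order is meaningful (file order; used for
    deterministic tie-breaking downstream).
    """

    data: pd.DataFrame
    schema: list[FeatureSchema]

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors -------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.schema]

    @property
    def X(self) -> np.ndarray:
        """Feature matrix in schema order (float64, NaN = missing)."""
        return self.data[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """Outcome vector: 1 = rare class, 0 = abundant class."""
        return self.data["outcome"].to_numpy(dtype=int)

    @property
    def patient_ids(self) -> list[str]:
        return self.data["patient_id"].astype(str).tolist()

    def with_X(self, X: np.ndarray) -> "CohortTable":
        """Copy of the table with the feature matrix replaced."""
        df = self.data.copy()
        df[self.feature_names] = X
        return CohortTable(df, self.schema)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        required = ["patient_id", *self.feature_names, "outcome"]
        missing_cols = [c for c in required if c not in df.columns]
        if missing_cols:
            raise SchemaError(f"missing columns: {missing_cols}")
        if "subtype" not in df.columns:
            df["subtype"] = "none"
        if df["outcome"].isna().any():
            rows = df.index[df["outcome"].isna()].tolist()
            raise CohortValidationError(f"outcome missing in rows {rows}")
        outcome = df["outcome"].to_numpy()
        if not np.isin(outcome, [0, 1]).all():
            raise CohortValidationError("outcome must be 0 (abundant) or 1 (rare)")
        bad_sub = set(df["subtype"]) - set(SUBTYPES)
        if bad_sub:
            raise CohortValidationError(f"unknown subtype labels: {sorted(bad_sub)}")
        for f in self.schema:
            col = df[f.name].to_numpy(dtype=float)
            obs = col[~np.isnan(col)]
            if f.kind == KIND_BINARY and not np.isin(obs, [0.0, 1.0]).all():
                bad = df.index[~df[f.name].isin([0, 1]) & df[f.name].notna()][0]
                raise CohortValidationError(
                    f"non-binary value in binary column {f.name!r}, row {bad}"
                )
            if f.kind == KIND_COUNT:
                bad_mask = ~np.isnan(col) & ((col < 0) | (col != np.round(col)))
                if bad_mask.any():
                    bad = int(np.argmax(bad_mask))
                    raise CohortValidationError(
                        f"count column {f.name!r} must hold non-negative integers (row {bad})"
                    )
            if f.kind == KIND_CONTINUOUS and np.isinf(obs).any():
                raise CohortValidationError(f"non-finite value in column {f.name!r}")

    def class_counts(self) -> tuple[int, int]:
        """(n_abundant, n_rare)."""
        y = self.y
        return int((y == 0).sum()), int((y == 1).sum())


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_cohort(path, schema: list[FeatureSchema] | None = None) -> CohortTable:
    """Read a cohort CSV written by :func:`write_cohort` (or hand-made).

    Missing feature values are empty cells or case-insensitive ``NA``.
    Raises :class:`SchemaError` on unknown/missing columns and
    :class:`CohortValidationError` on values that violate a feature's kind.
    """
    schema = schema if schema is not None else default_schema()
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    names = [f.name for f in schema]
    expected = {"patient_id", *names, "outcome", "subtype"}
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise SchemaError(f"unknown columns: {unknown}")
    if len(df) == 0:
        raise SchemaError("cohort file contains no data rows")

    def parse_cell(raw: str, row: int, col: str) -> float:
        s = raw.strip()
        if s == "" or s.upper() == "NA":
            return math.nan
        try:
            return float(s)
        except ValueError:
            raise CohortValidationError(
                f"cannot parse value {raw!r} (row {row}, column {col!r})"
            ) from None

    out = pd.DataFrame()
    if "patient_id" not in df.columns:
        raise SchemaError("missing patient_id column")
    out["patient_id"] = df["patient_id"].astype(str)
    for name in names:
        if name not in df.columns:
            raise SchemaError(f"missing feature column {name!r}")
        out[name] = [parse_cell(v, i, name) for i, v in enumerate(df[name])]
    outcome = [parse_cell(v, i, "outcome") for i, v in enumerate(df["outcome"])]
    if any(math.isnan(v) for v in outcome):
        raise CohortValidationError("outcome column contains missing values")
    out["outcome"] = [int(v) for v in outcome]
    out["subtype"] = df["subtype"] if "subtype" in df.columns else "none"
    return CohortTable(out, schema)


def write_cohort(table: CohortTable, path) -> None:
    """Write a cohort as CSV in fixed schema column order.

    Missing values become empty cells; continuous values are rounded to 6
    decimals (the round-trip contract), binary/count values are written as
    integers.
    """
    if not table.schema:
        raise SchemaError("empty feature schema")

    def fmt(value: float, kind: str) -> str:
        if isinstance(value, float) and math.isnan(value):
            return ""
        if kind in (KIND_BINARY, KIND_COUNT):
            return str(int(value))
        out = f"{float(value):.{_WRITE_DECIMALS}f}".rstrip("0").rstrip(".")
        return out if out not in ("", "-") else "0"

    cols = {"patient_id": table.data["patient_id"].astype(str)}
    for f in table.schema:
        cols[f.name] = [fmt(v, f.kind) for v in table.data[f.name]]
    cols["outcome"] = table.data["outcome"].astype(int).astype(str)
    cols["subtype"] = table.data["subtype"].astype(str)
    pd.DataFrame(cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# clinical-table summary
# ---------------------------------------------------------------------------

@dataclass
class FeatureSummary:
    name: str
    kind: str
    n_missing: int
    pct_missing: float
    median: float | None = None
    q1: float | None = None
    q3: float | None = None
    n_yes: int | None = None
    n_no: int | None = None
    pct_yes: float | None = None
    pct_no: float | None = None
    fully_missing: bool = False


@dataclass
class CohortSummary:
    """Per-feature marginal summary in the clinical-table convention:

    median and [q1, q3] for continuous/count variables, Yes/No absolute and
    percentage counts for binary variables, and the NA count per feature.
    Percentages are against the full cohort size, rounded to 1 decimal.
    """

    n_patients: int
    features: dict[str, FeatureSummary] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.features.values():
            rows.append(
                {
                    "feature": s.name,
                    "kind": s.kind,
                    "median": s.median,
                    "q1": s.q1,
                    "q3": s.q3,
                    "n_yes": s.n_yes,
                    "pct_yes": s.pct_yes,
                    "n_no": s.n_no,
                    "pct_no": s.pct_no,
                    "n_missing": s.n_missing,
                    "pct_missing": s.pct_missing,
                }
            )
        return pd.DataFrame(rows)


def _pct(count: int, n: int) -> float:
    return round(100.0 * count / n, 1)


def summarize_cohort(table: CohortTable) -> CohortSummary:
    """Marginal summary of a cohort (quantiles by linear interpolation)."""
    if table.n == 0:
        raise SchemaError("cannot summarize an empty cohort")
    n = table.n
    out = CohortSummary(n_patients=n)
    for f in table.schema:
        col = table.data[f.name].to_numpy(dtype=float)
        obs = col[~np.isnan(col)]
        n_missing = n - obs.size
        s = FeatureSummary(
            name=f.name, kind=f.kind, n_missing=n_missing, pct_missing=_pct(n_missing, n)
        )
        if obs.size == 0:
            s.fully_missing = True
        elif f.kind == KIND_BINARY:
            s.n_yes = int((obs == 1).sum())
            s.n_no = int((obs == 0).sum())
            s.pct_yes = _pct(s.n_yes, n)
            s.pct_no = _pct(s.n_no, n)
        else:
            q1, med, q3 = np.quantile(obs, [0.25, 0.5, 0.75])  # linear interpolation
            s.q1, s.median, s.q3 = float(q1), float(med), float(q3)
        out.features[f.name] = s
    return out
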