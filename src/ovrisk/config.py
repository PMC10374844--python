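"""Run configuration shared by the ensemble pipeline and the CLI.

Defaults replicate the published setup: 100 under-sampled sub-models per
ratio, ratios 1:1, 1:2, 1:3, a 100-tree selection forest, a linear SVM
with C = 1, and whole-dataset standardization before cross-validation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

STANDARDIZE_AS_PUBLISHED = "as-published"
STANDARDIZE_TRAIN_ONLY = "train-only"


@dataclass
class RunConfig:
    seed: int = 0
    n_models: int = 100
    ratios: tuple[int, ...] = (1, 2, 3)
    svm_c: float = 1.0
    svm_tol: float = 1e-4
    n_trees: int = 100
    standardize_mode: str = STANDARDIZE_AS_PUBLISHED
    keep_artifacts: bool = False

    def __post_init__(self) -> None:
        self.ratios = tuple(int(r) for r in self.ratios)
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if any(r < 1 for r in self.ratios) or not self.ratios:
            raise ValueError("ratios must be positive integers")
        if self.standardize_mode not in (STANDARDIZE_AS_PUBLISHED, STANDARDIZE_TRAIN_ONLY):
            raise ValueError(f"unknown standardize_mode {self.standardize_mode!r}")

    @classmethod
    def published_defaults(cls, seed: int = 0) -> "RunConfig":
        """Every knob pinned to the published configuration."""
        return cls(seed=seed)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ratios"] = list(self.ratios)
        return d

    def hash(self) -> str:
        """Short stable digest of the configuration, for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
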