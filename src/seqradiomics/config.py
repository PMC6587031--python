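"""Pipeline configuration and YAML round-trip."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

#: Elliptical-gate acceptance factors (a, b) per task, tuned by the grid
#: search to retain about half of the catalog on the study cohort.
DEFAULT_ACCEPTANCE_FACTORS = {
    "four_class": (0.60, 0.85),
    "tn_binary": (0.54, 0.76),
}

#: Final feature-set size after correlation pruning per task.
DEFAULT_FINAL_COUNT = {"four_class": 20, "tn_binary": 8}


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters.

    ``task`` is ``"four_class"`` (four IHC subtypes) or ``"tn_binary"``
    (triple-negative vs the rest). ``acceptance_factors`` are the semi-axes
    (a, b) of the elliptical coarse-selection gate in (p-value, CV-error)
    space; ``None`` selects the per-task default.
    """

    task: str = "four_class"
    acceptance_factors: tuple[float, float] | None = None
    auto_tune_factors: bool = False
    fine_top_k: int = 40
    corr_threshold: float = 0.4
    final_feature_count: int | None = None
    cv_folds: int = 5
    cv_rounds: int = 10
    seed: int = 0
    bin_count: int = 32
    nested: bool = False

    def __post_init__(self) -> None:
        if self.task not in ("four_class", "tn_binary"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.acceptance_factors is None:
            self.acceptance_factors = DEFAULT_ACCEPTANCE_FACTORS[self.task]
        a, b = self.acceptance_factors
        if not (0 < a <= 1 and 0 < b <= 1):
            raise ValueError(f"acceptance factors must lie in (0, 1], got {a}, {b}")
        self.acceptance_factors = (float(a), float(b))
        if self.final_feature_count is None:
            self.final_feature_count = DEFAULT_FINAL_COUNT[self.task]
        if not (0 < self.corr_threshold < 1):
            raise ValueError("corr_threshold must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.cv_rounds < 1:
            raise ValueError("cv_rounds must be >= 1")
        if self.bin_count < 2:
            raise ValueError("bin_count must be >= 2")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["acceptance_factors"] = list(self.acceptance_factors)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "acceptance_factors" in d and d["acceptance_factors"] is not None:
            d["acceptance_factors"] = tuple(d["acceptance_factors"])
        return cls(**d)
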