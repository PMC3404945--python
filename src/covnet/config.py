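"""Run configuration: YAML-backed settings for the end-to-end analysis."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .metrics import PATH_LENGTH_MODES
from .inference import GLOBAL_MEASURES, MIN_REPETITIONS

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Settings for ``covnet run`` / :func:`covnet.pipeline.run_full_analysis`."""

    group_a: str
    group_b: str
    out_dir: str = "covnet_results"
    covariates: list[str] = field(default_factory=lambda: ["age", "tbv"])
    density_min: float = 0.05
    density_max: float = 0.50
    density_step: float = 0.01
    repetitions: int = 1000
    ensemble_size: int = 20
    iterations_per_edge: int = 10
    path_length_mode: str = "component"
    pooled_confound_fit: bool = False
    sweep_measures: list[str] = field(default_factory=lambda: list(GLOBAL_MEASURES))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repetitions < MIN_REPETITIONS:
            raise ValueError(f"repetitions must be >= {MIN_REPETITIONS}")
        if not 0.0 < self.density_min <= self.density_max <= 1.0:
            raise ValueError("density range must satisfy 0 < min <= max <= 1")
        if self.density_step <= 0:
            raise ValueError("density_step must be positive")
        if self.path_length_mode not in PATH_LENGTH_MODES:
            raise ValueError(f"path_length_mode must be one of {PATH_LENGTH_MODES}")
        unknown = set(self.sweep_measures) - set(GLOBAL_MEASURES)
        if unknown:
            raise ValueError(f"unknown sweep measures: {sorted(unknown)}")
        if self.ensemble_size < 1 or self.iterations_per_edge < 1:
            raise ValueError("ensemble_size and iterations_per_edge must be positive")

    def validate_paths(self) -> None:
        for path in (self.group_a, self.group_b):
            if not Path(path).is_file():
                raise FileNotFoundError(f"input table not found: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
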