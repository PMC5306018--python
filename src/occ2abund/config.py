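"""Pipeline configuration with lossless YAML round-tripping.

Defaults follow the published workflow wherever it states a value: 15 repeats
of random 70/30 splits, six algorithms, leading-group/top-20 selection,
|r| > 0.7 covariate pruning, the >= 2 surveys x >= 50 species well-surveyed
rule over 1950–2014, and the five-nonzero-per-fold cross-validation rule with
a 10-fold ceiling.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .sdm import ALGORITHM_NAMES
from .synthetic import EffortModel, LandscapeConfig


def _tupleize(cls, d: dict):
    """Rebuild a dataclass from a dict, restoring tuple-typed fields."""
    kwargs = {}
    for f in fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if isinstance(v, list) and "tuple" in str(f.type):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


@dataclass
class PipelineConfig:
    """Everything the two-stage pipeline needs, in one serializable object."""

    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    effort: EffortModel = field(default_factory=EffortModel)
    seed: int = 0
    # stage 1
    algorithms: list[str] = field(default_factory=lambda: list(ALGORITHM_NAMES))
    repeats: int = 15
    split_fraction: float = 0.7
    selection_gap: float = 0.05
    fallback_k: int = 20
    deviation_threshold: float = 0.25
    correlation_threshold: float = 0.7
    hyperparameters: dict = field(default_factory=dict)  # per-algorithm overrides
    # occurrence prep
    min_surveys: int = 2
    min_species: int = 50
    year_window: tuple[int, int] = (1950, 2014)
    # abundance sampling + stage 2
    n_patch_source: int = 2000
    n_plot_source: int = 2000
    noise_sd: float = 2.0
    per_fold: int = 5
    max_k: int = 10
    min_nonzero: int = 30
    rf_params: dict = field(default_factory=dict)
    zero_cutoff: float | None = None

    def __post_init__(self):
        if isinstance(self.landscape, dict):
            self.landscape = _tupleize(LandscapeConfig, self.landscape)
        if isinstance(self.effort, dict):
            self.effort = _tupleize(EffortModel, self.effort)
        if isinstance(self.year_window, list):
            self.year_window = tuple(self.year_window)
        unknown = [a for a in self.algorithms if a not in ALGORITHM_NAMES]
        if unknown:
            raise ValueError(f"unknown algorithms {unknown}; registry: "
                             f"{ALGORITHM_NAMES}")

    @property
    def species(self) -> list[str]:
        return self.landscape.species

    def to_dict(self) -> dict:
        def plain(v):
            if isinstance(v, dict):
                return {k: plain(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [plain(x) for x in v]
            return v
        return plain(asdict(self))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return _tupleize(cls, d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
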