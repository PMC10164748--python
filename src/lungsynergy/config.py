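"""Analysis configuration with the study's published constants as defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Tunable decision constants for the whole pipeline.

    Defaults are the published decision rules: anti-inflammatory below 50%
    of the stimulated control, cytotoxic below 80% viability, significance
    at 0.05, FICI synergy cut-off 0.5 and antagonism cut-off 4, 4-level 1:4
    checkerboard ladders, and 2.5e5 host cells per well for MOI→CFU
    conversion.
    """

    threshold_activation_pct: float = 50.0
    threshold_viability_pct: float = 80.0
    alpha: float = 0.05
    alpha_normality: float = 0.05
    fici_synergy: float = 0.5
    fici_antagonism: float = 4.0
    n_levels: int = 4
    dilution: float = 4.0
    host_cells_per_well: int = 250000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("threshold_activation_pct", "threshold_viability_pct"):
            value = getattr(self, name)
            if not 0 < value < 100:
                raise ValueError(f"{name} must lie in (0, 100), got {value}")
        if not self.fici_synergy < self.fici_antagonism:
            raise ValueError("fici_synergy must be below fici_antagonism")
        if not 0 < self.alpha < 1 or not 0 < self.alpha_normality < 1:
            raise ValueError("alpha levels must lie in (0, 1)")
        if self.n_levels < 1 or self.dilution <= 1:
            raise ValueError("ladder needs n_levels >= 1 and dilution > 1")
        if self.host_cells_per_well <= 0:
            raise ValueError("host_cells_per_well must be positive")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def override(self, **kwargs) -> "AnalysisConfig":
        data = asdict(self)
        data.update({k: v for k, v in kwargs.items() if v is not None})
        return AnalysisConfig(**data)

    def echo_lines(self) -> list[str]:
        """Config echo embedded in every report header."""
        return [f"# config {name} = {value}" for name, value in asdict(self).items()]
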