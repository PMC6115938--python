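"""Pipeline configuration.

Every numeric threshold used anywhere in the pipeline lives here, with the
defaults the analysis was designed around: scaffolds are dropped below 10x
coverage or 200 nt; bidirectional-best-hit orthologs require 70% identity over
70% of the query length; AAI orthologs require 40% identity over 70% length at
e-value <= 1e-12; protein families cluster at 80% identity; putative species
are joined at 96% ANI and AAI (94% as the alternate check); unique proteins
count a database match at e-value <= 1e-10; COG comparisons use Fisher tests
at alpha 0.05; the carbon screen opens one source at a time at an uptake rate
of 10 mmol gDW^-1 h^-1 and calls growth above an objective flux of 1e-6.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class PipelineConfig:
    scaffold_min_coverage: float = 10.0
    scaffold_min_length: int = 200
    bbh_min_identity: float = 70.0
    bbh_min_coverage: float = 70.0
    aai_min_identity: float = 40.0
    aai_min_coverage: float = 70.0
    aai_max_evalue: float = 1e-12
    family_identity: float = 80.0
    species_threshold: float = 96.0
    species_threshold_alt: float = 94.0
    blast_hit_max_evalue: float = 1e-10
    fisher_alpha: float = 0.05
    panel_size: int = 163
    uptake_rate: float = 10.0
    growth_epsilon: float = 1e-6
    island_min_genes: int = 4
    island_max_gap: int = 3
    ani_fragment_length: int = 1000
    ani_min_fragment_identity: float = 70.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.scaffold_min_coverage < 0 or self.scaffold_min_length < 0:
            raise ConfigurationError("scaffold thresholds must be non-negative")
        for name in ("bbh_min_identity", "bbh_min_coverage", "aai_min_identity",
                     "aai_min_coverage", "family_identity", "species_threshold",
                     "species_threshold_alt"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ConfigurationError(f"{name}={v} outside [0, 100]")
        if self.aai_max_evalue < 0 or self.blast_hit_max_evalue < 0:
            raise ConfigurationError("e-value thresholds must be non-negative")
        if not 0 <= self.fisher_alpha <= 1:
            raise ConfigurationError("fisher_alpha must be in [0, 1]")
        if self.uptake_rate < 0:
            raise ConfigurationError("uptake_rate must be non-negative")
        if self.island_min_genes < 1 or self.island_max_gap < 0:
            raise ConfigurationError("invalid island detection parameters")
        if self.ani_fragment_length < 100:
            raise ConfigurationError("ani_fragment_length must be >= 100")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
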