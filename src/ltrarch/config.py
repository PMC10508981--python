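"""Run configuration: one YAML file naming every threshold the pipeline uses."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class BlueprintConfig:
    structure: str
    count: int = 1
    ltr_length: int = 300
    ltr_divergence: float = 0.0
    domain_divergence: float = 0.0
    degrade_native_rh: bool = False
    degrade_distal_arh: bool = False


@dataclass
class GenomeConfig:
    genome_id: str
    length: int = 200_000
    taxon: str = ""
    gc: float = 0.4
    elements: list[BlueprintConfig] = field(default_factory=list)


@dataclass
class RunConfig:
    seed: int = 1
    genomes: list[GenomeConfig] = field(default_factory=list)

    # mining
    pseudocount: float = 1.0
    min_bits_frac: float = 0.4
    max_gap: int = 10_000
    flank: int = 5000
    ltr_min_len: int = 100
    ltr_min_identity: float = 80.0

    # classification
    min_orf_aa: int = 50
    arh_linker_max: int = 600
    identity_threshold: float = 80.0

    # degradation
    degraded_threshold: int = 1

    # phylogenetics
    support_threshold: float = 95.0
    n_reps: int = 100
    poisson_correct: bool = False

    def validate(self) -> None:
        checks = [
            (0 <= self.min_bits_frac <= 1, "min_bits_frac must be in [0,1]"),
            (self.max_gap > 0, "max_gap must be positive"),
            (self.flank >= self.ltr_min_len, "flank must be >= ltr_min_len"),
            (0 <= self.ltr_min_identity <= 100, "ltr_min_identity must be a percentage"),
            (self.min_orf_aa > 0, "min_orf_aa must be positive"),
            (0 <= self.identity_threshold <= 100, "identity_threshold must be a percentage"),
            (0 <= self.degraded_threshold <= 4, "degraded_threshold must be in 0..4"),
            (0 <= self.support_threshold <= 100, "support_threshold must be a percentage"),
            (self.n_reps >= 1, "n_reps must be >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigError(msg)
        for g in self.genomes:
            for b in g.elements:
                if not 0 <= b.ltr_divergence <= 0.5 or not 0 <= b.domain_divergence <= 0.5:
                    raise ConfigError(f"{g.genome_id}: divergences must be in [0, 0.5]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        genomes = []
        for g in data.pop("genomes", []):
            g = dict(g)
            elements = [BlueprintConfig(**b) for b in g.pop("elements", [])]
            genomes.append(GenomeConfig(elements=elements, **g))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(genomes=genomes, **data)
        cfg.validate()
        return cfg

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
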