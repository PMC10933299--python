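"""Pipeline configuration: YAML-backed, strictly validated.

Unknown keys are rejected up front so a typo in a config never silently
falls back to a default. Every pipeline run writes a resolved-config
snapshot next to its outputs, so a result directory is self-describing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["ConfigError", "PipelineConfig"]

DEFAULT_GENOTYPES = ("iRFP", "WT", "A282V", "M446R", "P497H", "P497S", "P506T")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class ClassifierSettings:
    threshold: float = 0.62
    sd_convention: str = "population"


@dataclass
class FrapSettings:
    temperature_k: float = 310.0
    stokes_radius_nm: float = 4.5


@dataclass
class SurvivalSettings:
    reference: str = "iRFP"
    strata: str | None = "experiment_id"


@dataclass
class FluxSettings:
    mode: str = "as-printed"


@dataclass
class PathSettings:
    tracks: str | None = None
    frap_traces: str | None = None
    decay_traces: str | None = None


@dataclass
class PipelineConfig:
    """Resolved settings for an end-to-end run.

    When ``paths.tracks`` is None the cohort is simulated from the seed;
    likewise for FRAP and decay inputs, so a bare default config runs the
    full simulate-and-analyze loop.
    """

    seed: int = 0
    genotypes: tuple[str, ...] = DEFAULT_GENOTYPES
    n_cells: int = 1400
    paths: PathSettings = field(default_factory=PathSettings)
    classifier: ClassifierSettings = field(default_factory=ClassifierSettings)
    frap: FrapSettings = field(default_factory=FrapSettings)
    survival: SurvivalSettings = field(default_factory=SurvivalSettings)
    flux: FluxSettings = field(default_factory=FluxSettings)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        kwargs = {}
        nested = {
            "paths": PathSettings,
            "classifier": ClassifierSettings,
            "frap": FrapSettings,
            "survival": SurvivalSettings,
            "flux": FluxSettings,
        }
        top_fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - top_fields
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for name, sub_cls in nested.items():
            sub = data.pop(name, {}) or {}
            sub_fields = {f.name for f in dataclasses.fields(sub_cls)}
            bad = set(sub) - sub_fields
            if bad:
                raise ConfigError(f"unknown keys in {name!r}: {sorted(bad)}")
            kwargs[name] = sub_cls(**sub)
        if "genotypes" in data:
            data["genotypes"] = tuple(data["genotypes"])
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["genotypes"] = list(self.genotypes)
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
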