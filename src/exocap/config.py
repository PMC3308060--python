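"""Run configuration: every pipeline threshold in one place.

Defaults reproduce the published pipeline settings: proper-pair span 1000,
probe overlap 20, required mapping quality 60, collapse quality cap 60,
consensus-quality call filter 50, gold-standard quality 100, coverage breadth
thresholds {1, 20}.  Unknown keys in a config file are errors, not warnings —
a silently ignored typo would corrupt threshold semantics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping, Tuple

from .simulate import TRUSEQ_ADAPTER_R1, TRUSEQ_ADAPTER_R2

__all__ = ["PipelineConfig", "SimulationConfig", "RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid configuration key or value."""


@dataclass
class PipelineConfig:
    """Lane- and sample-level processing thresholds."""

    max_span: int = 1000
    min_probe_overlap: int = 20
    required_mq: int = 60
    quality_cap: int = 60
    call_min_quality: int = 50
    gold_min_quality: int = 100
    breadth_thresholds: Tuple[int, ...] = (1, 20)
    clip_min_overlap: int = 10
    clip_max_mismatch_rate: float = 0.1
    het_prior: float = 1e-3
    hom_alt_prior: float = 5e-4
    adapter1: str = TRUSEQ_ADAPTER_R1
    adapter2: str = TRUSEQ_ADAPTER_R2

    def __post_init__(self) -> None:
        if self.max_span < 1 or self.min_probe_overlap < 1:
            raise ConfigError("span and probe-overlap thresholds must be positive")
        if not 0 <= self.required_mq <= 255:
            raise ConfigError("required_mq out of range")
        for name in ("quality_cap", "call_min_quality", "gold_min_quality"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not 0.0 <= self.clip_max_mismatch_rate <= 1.0:
            raise ConfigError("clip_max_mismatch_rate must be in [0, 1]")
        if not (0.0 < self.het_prior and 0.0 < self.hom_alt_prior
                and self.het_prior + self.hom_alt_prior < 1.0):
            raise ConfigError("priors must be positive and sum below 1")
        self.breadth_thresholds = tuple(sorted(int(t) for t in self.breadth_thresholds))
        if any(t <= 0 for t in self.breadth_thresholds):
            raise ConfigError("breadth thresholds must be positive")


@dataclass
class SimulationConfig:
    """Synthetic capture-experiment conditions."""

    chrom_lengths: Mapping[str, int] = field(default_factory=lambda: {"chr1": 2_000_000})
    gc_fraction: float = 0.41
    snv_rate: float = 1e-3
    het_fraction: float = 0.6
    transition_prob: float = 2.0 / 3.0
    n_targets: int = 400
    target_length_mean: float = 150.0
    target_length_sd: float = 35.0
    probe_margin: int = 0
    untargeted_fraction: float = 0.0
    insert_profile: str = "gel"  # "gel" | "bead"
    read_length: int = 76
    error_rate: float = 0.005
    duplicate_rate: float = 0.10
    off_probe_fraction: float = 0.12
    n_pairs: int = 80_000
    n_lanes: int = 1

    def library_profile(self):
        from .simulate import LibraryProfile, bead_insert_model, gel_insert_model

        model = gel_insert_model() if self.insert_profile == "gel" else bead_insert_model()
        return LibraryProfile(
            read_length=self.read_length,
            insert_model=model,
            error_rate=self.error_rate,
            duplicate_rate=self.duplicate_rate,
            off_probe_fraction=self.off_probe_fraction,
        )


@dataclass
class RunConfig:
    """Top-level configuration: simulation conditions + pipeline thresholds."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)
    seed: int = 0

    @classmethod
    def from_mapping(cls, data: Mapping[str, object]) -> "RunConfig":
        """Build from a flat key/value mapping; unknown keys raise
        :class:`ConfigError` listing the valid keys."""
        sim_fields = {f.name: f for f in fields(SimulationConfig)}
        pipe_fields = {f.name: f for f in fields(PipelineConfig)}
        sim_kw, pipe_kw = {}, {}
        seed = 0
        for key, value in data.items():
            if key == "seed":
                seed = int(value)  # type: ignore[arg-type]
            elif key in sim_fields:
                sim_kw[key] = value
            elif key in pipe_fields:
                pipe_kw[key] = value
            else:
                valid = sorted(["seed", *sim_fields, *pipe_fields])
                raise ConfigError(
                    f"unknown configuration key {key!r}; valid keys: {', '.join(valid)}"
                )
        return cls(
            simulation=SimulationConfig(**sim_kw),  # type: ignore[arg-type]
            pipeline=PipelineConfig(**pipe_kw),  # type: ignore[arg-type]
            seed=seed,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigError(f"{path}: expected a flat key/value mapping")
        return cls.from_mapping(data)

    def to_flat_dict(self) -> dict:
        out = {"seed": self.seed}
        out.update(dataclasses.asdict(self.simulation))
        out.update(dataclasses.asdict(self.pipeline))
        return out
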