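"""Declarative pipeline configuration.

Every default the underlying method leaves open (smoothing window, DTW
template margins, activation threshold, basis dimension, ridge penalty,
simulation defaults, seed) lives here so experiments are reproducible from
a single flat YAML file.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .core_io import FacekinError
from .health_scores import FLRConfig
from .indicators import IndicatorConfig
from .registration import RegistrationConfig
from .synthetic import DEFAULT_CLASS_MIX, DEFAULT_NOISE_SD, DEFAULT_SAMPLING_HZ

__all__ = ["OLRSettings", "SimulationSettings", "PipelineConfig"]


@dataclass
class OLRSettings:
    tol: float = 1e-8
    max_iter: int = 500

    def validate(self) -> None:
        if self.tol <= 0 or self.max_iter < 1:
            raise FacekinError("invalid OLR settings")


@dataclass
class SimulationSettings:
    n_sessions: int = 122
    class_mix: tuple[float, float, float, float] = DEFAULT_CLASS_MIX
    noise_sd: float = DEFAULT_NOISE_SD
    sampling_hz: tuple[float, float] = DEFAULT_SAMPLING_HZ

    def validate(self) -> None:
        if self.n_sessions < 1:
            raise FacekinError("n_sessions must be >= 1")
        if abs(sum(self.class_mix) - 1.0) > 1e-9 or any(p < 0 for p in self.class_mix):
            raise FacekinError("class_mix must be probabilities summing to 1")
        if self.noise_sd < 0:
            raise FacekinError("noise_sd must be nonnegative")


@dataclass
class PipelineConfig:
    """All tunables of the pipeline; a fully defaulted config is valid."""

    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    indicators: IndicatorConfig = field(default_factory=IndicatorConfig)
    flr: FLRConfig = field(default_factory=FLRConfig)
    olr: OLRSettings = field(default_factory=OLRSettings)
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    seed: int = 0

    def validate(self) -> None:
        self.registration.validate()
        self.olr.validate()
        self.simulation.validate()
        if self.flr.basis_dim < 1 or self.flr.penalty < 0:
            raise FacekinError("invalid FLR settings")
        if self.indicators.baseline_mode not in ("rest_window", "first_sample"):
            raise FacekinError("invalid baseline mode")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"]["class_mix"] = list(self.simulation.class_mix)
        d["simulation"]["sampling_hz"] = list(self.simulation.sampling_hz)
        return d

    def to_yaml(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True),
                              encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        cfg = cls()
        for section, factory in (
            ("registration", RegistrationConfig),
            ("indicators", IndicatorConfig),
            ("flr", FLRConfig),
            ("olr", OLRSettings),
            ("simulation", SimulationSettings),
        ):
            sub = data.get(section, {})
            if not isinstance(sub, dict):
                raise FacekinError(f"config section {section!r} must be a mapping")
            obj = factory()
            for key, value in sub.items():
                if not hasattr(obj, key):
                    raise FacekinError(f"unknown config key {section}.{key}")
                if key in ("class_mix", "sampling_hz"):
                    value = tuple(value)
                setattr(obj, key, value)
            setattr(cfg, section, obj)
        cfg.seed = int(data.get("seed", 0))
        cfg.validate()
        return cfg

    def digest(self) -> str:
        """Stable hash of the configuration for run manifests."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
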