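"""Nested configuration for the denoising pipeline, YAML-loadable."""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "LowpassConfig",
    "PeriodConfig",
    "CicaConfig",
    "LmsConfig",
    "FftLmsConfig",
    "MafConfig",
    "ScoringConfig",
    "PipelineConfig",
]


@dataclass
class LowpassConfig:
    pass_hz: float = 4.0
    stop_hz: float = 8.0
    min_atten_db: float = 20.0


@dataclass
class PeriodConfig:
    min_hz: float = 0.5
    max_hz: float = 4.0


@dataclass
class CicaConfig:
    contrast: str = "logcosh"
    rho: float = 1.0
    xi: float | None = None
    max_iter: int = 500
    tol: float = 1e-7
    penalty_init: float = 10.0


@dataclass
class LmsConfig:
    order: int = 16
    mu: float = 0.001
    normalize_mu: bool = True
    passes: int = 3


@dataclass
class FftLmsConfig:
    pulsatile_hz: tuple[float, float] = (0.5, 4.0)
    respiratory_hz: tuple[float, float] = (0.2, 0.35)


@dataclass
class MafConfig:
    window_s: float = 0.1


@dataclass
class ScoringConfig:
    """RRMSE scoring window: skip the initial adaptive-filter transient."""

    skip_s: float = 2.0


@dataclass
class PipelineConfig:
    fs: float = 200.0
    lowpass: LowpassConfig = field(default_factory=LowpassConfig)
    dc_pole: float = 0.992
    period: PeriodConfig = field(default_factory=PeriodConfig)
    reference_duty: float = 0.2
    cica: CicaConfig = field(default_factory=CicaConfig)
    lms: LmsConfig = field(default_factory=LmsConfig)
    fftlms: FftLmsConfig = field(default_factory=FftLmsConfig)
    maf: MafConfig = field(default_factory=MafConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            val = data[f.name]
            sub = {
                "lowpass": LowpassConfig, "period": PeriodConfig,
                "cica": CicaConfig, "lms": LmsConfig, "fftlms": FftLmsConfig,
                "maf": MafConfig, "scoring": ScoringConfig,
            }.get(f.name)
            if sub is not None and isinstance(val, dict):
                val = sub(**val)
            elif f.name == "fftlms" and isinstance(val, dict):
                val = FftLmsConfig(**val)
            kwargs[f.name] = val
        cfg = cls(**kwargs)
        # YAML lists -> tuples for band intervals
        cfg.fftlms.pulsatile_hz = tuple(cfg.fftlms.pulsatile_hz)
        cfg.fftlms.respiratory_hz = tuple(cfg.fftlms.respiratory_hz)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
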