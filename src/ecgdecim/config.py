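"""Run configuration shared by the CLI subcommands.

A flat-sectioned YAML file mirrors the dataclass fields below; values on
the command line override file values, which override the built-in
defaults (the published operating point: B=390, K=80, F1=8, F2=20,
W1=97 ms, W2=611 ms, beta=8, 75 ms match tolerance).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml


@dataclass(frozen=True)
class ResampleConfig:
    B: float = 390.0
    K: float = 80.0
    stopband_db: float = 60.0


@dataclass(frozen=True)
class TermaConfig:
    f1: float = 8.0
    f2: float = 20.0
    filter_order: int = 3
    w1_s: float = 0.097
    w2_s: float = 0.611
    beta: float = 8.0
    beta_scale: float = 0.01


@dataclass(frozen=True)
class EvalConfig:
    tol_s: float = 0.075
    prd_denominator: str = "reconstructed"
    prd_demean: bool = False
    bits_in: float = 11.0


@dataclass(frozen=True)
class GridConfig:
    b_min: float = 360.0
    b_max: float = 500.0
    b_step: float = 10.0
    k_min: float = 50.0
    k_max: float = 360.0
    k_step: float = 10.0


@dataclass(frozen=True)
class RunConfig:
    resample: ResampleConfig = field(default_factory=ResampleConfig)
    terma: TermaConfig = field(default_factory=TermaConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        sections = {}
        for f in fields(cls):
            if f.name == "log_level":
                continue
            section_cls = f.default_factory  # type: ignore[misc]
            raw = data.get(f.name, {}) or {}
            known = {x.name for x in fields(section_cls)}
            unknown = set(raw) - known
            if unknown:
                raise ValueError(f"unknown config keys in [{f.name}]: {sorted(unknown)}")
            sections[f.name] = section_cls(**raw)
        return cls(log_level=data.get("log_level", "INFO"), **sections)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def override(self, section: str, **values) -> "RunConfig":
        """Copy with non-None values replacing fields of one section."""
        current = getattr(self, section)
        updates = {k: v for k, v in values.items() if v is not None}
        return replace(self, **{section: replace(current, **updates)})
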