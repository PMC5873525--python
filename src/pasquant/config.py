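"""Run configuration: one YAML mapping drives the whole pipeline.

All physical constants and conventions are overridable here so any
reference condition can be reproduced exactly.  The configuration
round-trips losslessly through ``to_dict``/``from_dict``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .imaging import FilterRules, ImageCalibration
from .physics import AirEnvironment, DepositionSettings, GammaModel, MaterialProperties
from .quantify import CONVENTIONS, BlankGroup, FractionConvention, SamplerConfig


@dataclass
class RunConfig:
    calibration: ImageCalibration = field(default_factory=ImageCalibration)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    material: MaterialProperties = field(default_factory=MaterialProperties)
    environment: AirEnvironment = field(default_factory=AirEnvironment)
    deposition: DepositionSettings = field(default_factory=DepositionSettings)
    model: GammaModel = field(default_factory=GammaModel)
    filter_rules: FilterRules | None = None
    fractions: list[str] = field(default_factory=lambda: ["pm10", "pm2.5", "respirable"])
    threshold_method: str = "renyi_entropy"
    threshold_alpha: float = 1.0
    blank_groups: dict[str, BlankGroup] = field(default_factory=dict)
    blank_assignment: dict[str, str] = field(default_factory=dict)  # location -> group
    seed: int = 0

    def resolved_filter_rules(self) -> FilterRules:
        if self.filter_rules is not None:
            return self.filter_rules
        return FilterRules.for_calibration(self.calibration)

    def conventions(self) -> list[FractionConvention]:
        out = []
        for name in self.fractions:
            key = name.lower()
            if key not in CONVENTIONS:
                raise ConfigurationError(
                    f"unknown fraction {name!r}; known: {sorted(CONVENTIONS)}"
                )
            out.append(CONVENTIONS[key])
        return out

    def blank_group_for(self, location: str) -> BlankGroup:
        if location not in self.blank_assignment:
            raise ConfigurationError(f"no blank group assigned to location {location!r}")
        group = self.blank_assignment[location]
        if group not in self.blank_groups:
            raise ConfigurationError(f"blank group {group!r} is not defined")
        return self.blank_groups[group]

    def to_dict(self) -> dict:
        return {
            "calibration": asdict(self.calibration),
            "sampler": asdict(self.sampler),
            "material": asdict(self.material),
            "environment": asdict(self.environment),
            "deposition": asdict(self.deposition),
            "model": asdict(self.model),
            "filter_rules": asdict(self.filter_rules) if self.filter_rules else None,
            "fractions": list(self.fractions),
            "threshold_method": self.threshold_method,
            "threshold_alpha": self.threshold_alpha,
            "blank_groups": {
                label: {"label": g.label, "concentrations": g.concentrations}
                for label, g in self.blank_groups.items()
            },
            "blank_assignment": dict(self.blank_assignment),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        try:
            blank_groups = {
                label: BlankGroup(**spec)
                for label, spec in (data.get("blank_groups") or {}).items()
            }
            filter_spec = data.get("filter_rules")
            return cls(
                calibration=ImageCalibration(**(data.get("calibration") or {})),
                sampler=SamplerConfig(**(data.get("sampler") or {})),
                material=MaterialProperties(**(data.get("material") or {})),
                environment=AirEnvironment(**(data.get("environment") or {})),
                deposition=DepositionSettings(**(data.get("deposition") or {})),
                model=GammaModel(**(data.get("model") or {})),
                filter_rules=FilterRules(**filter_spec) if filter_spec else None,
                fractions=list(data.get("fractions", ["pm10", "pm2.5", "respirable"])),
                threshold_method=data.get("threshold_method", "renyi_entropy"),
                threshold_alpha=float(data.get("threshold_alpha", 1.0)),
                blank_groups=blank_groups,
                blank_assignment=dict(data.get("blank_assignment") or {}),
                seed=int(data.get("seed", 0)),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"invalid configuration: {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
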