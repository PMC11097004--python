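"""Serialisable experiment configuration with strict key checking."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .classify import RFConfig
from .synthetic import (DEFAULT_BUDGET, DEFAULT_CALIBRATION_S,
                        DEFAULT_MEAN_BOUT_S, DEFAULT_REGIMES, BehaviourRegime)


@dataclass
class CalibrationSettings:
    n_individuals: int = 9
    per_behaviour_s: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CALIBRATION_S))
    sample_rate_hz: float = 40.0


@dataclass
class FeatureSettings:
    static_window_s: float = 2.0
    smooth_window_s: float = 2.0
    se_window_s: float = 2.0


@dataclass
class DatasetSettings:
    cap_s: float = 60.0
    train_fraction: float = 0.6
    split_by_bout: bool = False


@dataclass
class DeploymentSettings:
    n_deployments: int = 5
    #: desk-scale default; the full-deployment study length is 2.74 days
    duration_days: float = 2.0 / 24.0
    budget: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BUDGET))
    mean_bout_s: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEAN_BOUT_S))
    full_scale: bool = False  # True -> 2.74-day deployments

    @property
    def effective_duration_days(self) -> float:
        return 2.74 if self.full_scale else self.duration_days


@dataclass
class ComparisonSettings:
    reference: str = "rule_tree"  # "rule_tree" | "truth"
    subsample_first_15min: bool = True
    exclude_rest_rerun: bool = True


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce a full experiment, serialisable to YAML."""

    seed: int = 0
    calibration: CalibrationSettings = field(default_factory=CalibrationSettings)
    features: FeatureSettings = field(default_factory=FeatureSettings)
    datasets: DatasetSettings = field(default_factory=DatasetSettings)
    rf: RFConfig = field(default_factory=RFConfig)
    deployment: DeploymentSettings = field(default_factory=DeploymentSettings)
    comparison: ComparisonSettings = field(default_factory=ComparisonSettings)
    regimes: dict[str, BehaviourRegime] = field(
        default_factory=lambda: dict(DEFAULT_REGIMES))
    out_dir: str = "results"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["regimes"] = {name: asdict(r) for name, r in self.regimes.items()}
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        cfg = cls()
        sections = {
            "calibration": CalibrationSettings, "features": FeatureSettings,
            "datasets": DatasetSettings, "rf": RFConfig,
            "deployment": DeploymentSettings, "comparison": ComparisonSettings,
        }
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key, value in d.items():
            if key in sections:
                section_cls = sections[key]
                valid = {f.name for f in fields(section_cls)}
                bad = set(value) - valid
                if bad:
                    raise ValueError(f"unknown key(s) in [{key}]: {sorted(bad)}")
                setattr(cfg, key, section_cls(**value))
            elif key == "regimes":
                regimes = {}
                for name, params in value.items():
                    valid = {f.name for f in fields(BehaviourRegime)}
                    bad = set(params) - valid
                    if bad:
                        raise ValueError(
                            f"unknown key(s) in regime {name!r}: {sorted(bad)}")
                    params = {"name": name, **params}
                    regimes[name] = BehaviourRegime(**params)
                cfg.regimes = regimes
            else:
                setattr(cfg, key, value)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
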