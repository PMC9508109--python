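"""Pipeline configuration: one YAML file with per-stage sections.

All randomness flows from the single root ``seed``; each stage derives its
own child seed deterministically. Every run writes the resolved
configuration beside its outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .gait import CONDITIONS


@dataclass
class RigConfig:
    scene_center: tuple = (0.3, 0.0, 0.1)
    distance: float = 1.5
    focal_px: float = 4500.0
    principal: tuple = (600.0, 600.0)
    lateral_tilt_deg: float = 0.0
    cube_spheres_per_axis: int = 3
    cube_spacing: float = 0.05


@dataclass
class FeatureConfig:
    D: int | None = None          # default: signal dim + n_distractors
    noise_sd: float = 0.01        # 1% of per-channel signal SD
    n_distractors: int = 8


@dataclass
class RegressorConfig:
    #: near-interpolation operating point for the synthetic pipeline;
    #: the library-level defaults are C=1, epsilon=0.1
    C: float = 1e6
    epsilon: float = 0.01
    M: int = 10


@dataclass
class EventConfig:
    use_truth: bool = True        # ground-truth (digitized) events by default
    height_threshold: float = 0.0008
    speed_fraction: float | None = None
    hysteresis: int = 5


@dataclass
class StatsConfig:
    conditions: tuple = ("up_2.5cm", "up_5cm", "down_2.5cm", "down_5cm")
    variables: tuple = ("hip_flexion", "hip_abduction", "eff_leg_angle")
    n_individuals: int = 8
    individual_sd_deg: float = 3.0
    trial_sd_deg: float = 1.0
    response: str = "multivariate"


@dataclass
class PipelineConfig:
    condition: str = "level"
    seed: int = 0
    fps: float = 500.0
    n_strides: int = 2
    pixel_noise_sd: float = 0.5
    outdir: str = "quailkin_run"
    rig: RigConfig = field(default_factory=RigConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    regressor: RegressorConfig = field(default_factory=RegressorConfig)
    events: EventConfig = field(default_factory=EventConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.fps <= 0 or self.n_strides < 1:
            raise ValueError("fps must be > 0 and n_strides >= 1")
        if self.pixel_noise_sd < 0:
            raise ValueError("pixel_noise_sd must be >= 0")
        if self.regressor.M < 1 or self.regressor.C <= 0 \
                or self.regressor.epsilon < 0:
            raise ValueError("invalid regressor hyperparameters")
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ValueError("seed must be a non-negative integer")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed below 2**31."""
        offsets = {"simulate": 11, "features": 23, "pixel_noise": 37,
                   "track": 41, "stats": 53}
        return (self.seed * 1009 + offsets.get(stage, 97)) % (2 ** 31)

    def to_dict(self) -> dict:
        # JSON round trip normalizes tuples to lists so that a config
        # written to YAML and reloaded compares equal
        return json.loads(json.dumps(asdict(self)))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (("rig", RigConfig), ("features", FeatureConfig),
                         ("regressor", RegressorConfig),
                         ("events", EventConfig), ("stats", StatsConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def write(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(
            json.loads(json.dumps(self.to_dict())), sort_keys=True))
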