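"""Run configuration: one human-readable YAML file drives the pipeline.

Defaults mirror the emulated study's acquisition settings (200 Hz plate and
camera rates, 25 Hz low-pass cutoff, 2-5 accepted gait cycles with <15%
velocity drift).  Values the study leaves unstated (filament set, staircase
bound, noise levels) are documented assumptions in ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .assays import DEFAULT_FILAMENTS_G
from .exceptions import ConfigError


@dataclass
class RunConfig:
    seed: int = 0
    # cohort design
    n_per_group: dict = field(default_factory=lambda: {
        "naive": 4, "sham": 6, "operated": 6})
    days: list = field(default_factory=lambda: [9, 16, 23])
    gait_trials_per_session: int = 3
    grf_trials_per_session: int = 2
    incapacitance_trials: int = 5
    # gait generation / validity
    n_cycles: int = 4
    timing_noise_sd_s: float = 0.002
    min_cycles: int = 2
    max_cycles: int = 5
    max_velocity_drift: float = 0.15
    # force plate
    sample_rate_hz: float = 200.0
    filter_cutoff_hz: float = 25.0
    filter_order: int = 4
    stance_threshold_frac: float = 0.025
    grid_points: int = 101
    grf_noise_sd_N: float = 0.01
    # video
    simulate_video: bool = True
    frame_rate_hz: float = 200.0
    calibration_cm_per_px: float = 0.1
    video_frames: int = 40
    video_noise_sd: float = 2.0
    # assays
    filament_set_g: list = field(
        default_factory=lambda: list(DEFAULT_FILAMENTS_G))
    # statistics
    alpha: float = 0.05
    p_adjust: str | None = None  # None or "bh" for the correlation table

    def validate(self) -> "RunConfig":
        checks = [
            (self.seed >= 0, "seed must be non-negative"),
            (all(n >= 2 for n in self.n_per_group.values()),
             "need at least 2 animals per group"),
            (len(self.days) >= 1, "need at least one timepoint"),
            (self.gait_trials_per_session >= 1, "need >= 1 gait trial"),
            (self.grf_trials_per_session >= 1, "need >= 1 force trial"),
            (2 <= self.n_cycles, "n_cycles must be >= 2"),
            (0 < self.min_cycles <= self.max_cycles,
             "cycle bounds must satisfy 0 < min <= max"),
            (0 < self.max_velocity_drift < 1,
             "velocity drift bound must lie in (0, 1)"),
            (self.sample_rate_hz >= 200,
             "sample_rate_hz below the 200 Hz plate rate"),
            (0 < self.filter_cutoff_hz < self.sample_rate_hz / 2,
             "filter cutoff must lie below Nyquist"),
            (self.filter_order >= 1, "filter order must be >= 1"),
            (0 < self.stance_threshold_frac < 0.5,
             "stance threshold fraction must lie in (0, 0.5)"),
            (self.grid_points >= 11, "grid_points must be >= 11"),
            (self.frame_rate_hz > 0, "frame rate must be positive"),
            (self.calibration_cm_per_px > 0,
             "calibration must be positive"),
            (self.video_frames >= 2, "need at least 2 video frames"),
            (len(self.filament_set_g) >= 2
             and all(f > 0 for f in self.filament_set_g)
             and sorted(self.filament_set_g) == list(self.filament_set_g),
             "filament set must be >= 2 positive ascending forces"),
            (0 < self.alpha < 1, "alpha must lie in (0, 1)"),
            (self.p_adjust in (None, "bh"),
             "p_adjust must be null or 'bh'"),
        ]
        for ok, message in checks:
            if not ok:
                raise ConfigError(message)
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"could not parse {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError(f"{path} does not contain a mapping")
        return cls.from_dict(data)
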