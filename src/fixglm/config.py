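"""Validated run configuration for the end-to-end pipeline."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional

import yaml
from pydantic import BaseModel, Field, field_validator


class DetectorConfig(BaseModel):
    velocity_deg_s: float = 30.0
    acceleration_deg_s2: float = 8000.0
    motion_deg: float = 0.1
    gaze_rate_hz: float = 1000.0
    gaze_jitter_deg: float = 0.02


class RejectionConfig(BaseModel):
    variance_sd_multiplier: float = 3.0
    min_fixations: int = 2
    min_epochs_per_condition: int = 5


class StageToggles(BaseModel):
    simulate: bool = True
    detect: bool = True
    preprocess: bool = True
    estimate: bool = True
    stats: bool = True
    power: bool = True


class ModulationConfig(BaseModel):
    condition: str
    site: str
    window_ms: tuple[float, float]
    offset_uv: float
    target: str = "s"


class RunConfig(BaseModel):
    """Everything a pipeline run needs; validated before any stage runs."""

    seed: int = 0
    rate_hz: float = 500.0
    n_participants: int = 3
    composition: dict[str, int] = Field(default_factory=lambda: {
        "neutral": 6, "happiness": 4, "surprise": 4, "fear": 2, "disgust": 4})
    rating_accuracy: float = 0.9
    noise_sd_uv: float = 5.0
    noise_exponent: float = 1.0
    epoch_window_ms: tuple[float, float] = (-200.0, 2000.0)
    baseline_ms: tuple[float, float] = (-200.0, 0.0)
    estimation_windows_ms: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {
            "s": (-200.0, 800.0), "fp1": (-200.0, 600.0),
            "fp2plus": (-200.0, 600.0), "sp": (-50.0, 100.0)})
    modulations: list[ModulationConfig] = Field(default_factory=list)
    detector: DetectorConfig = Field(default_factory=DetectorConfig)
    rejection: RejectionConfig = Field(default_factory=RejectionConfig)
    alpha: float = 0.05
    stages: StageToggles = Field(default_factory=StageToggles)
    power_participants: list[int] = Field(default_factory=lambda: [10, 19, 30])
    power_trials: list[int] = Field(default_factory=lambda: [5, 13, 25])
    power_reps: int = 200
    power_effect_uv: float = 1.5
    compute_condition_number: bool = False
    out_dir: Optional[str] = None

    @field_validator("rate_hz")
    @classmethod
    def _rate_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("rate_hz must be > 0")
        return v

    @field_validator("rating_accuracy")
    @classmethod
    def _acc_prob(cls, v: float) -> float:
        if not 0 <= v <= 1:
            raise ValueError("rating_accuracy must lie in [0, 1]")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json")))
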