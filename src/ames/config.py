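"""Run configuration: every pipeline parameter in one validated object.

The defaults reproduce the study's stated constants — 80.3 Hz sampling,
0.2-5 Hz band-pass, 50-point resampling, 4-mm / 1-Hz templates with 1:1
and 2:1 lift:thrust timing, alpha = 0.05 — plus the artifact's own
segmentation constants and simulator parameterization. Configurations
round-trip through YAML and carry a content hash for provenance logging.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Tuple

import yaml
from pydantic import BaseModel, Field, model_validator

from .preprocess import FilterSpec
from .simulate import (
    GROUPS,
    LearningCurve,
    SimulationParams,
    StudyDesign,
    default_params_by_group,
)


class FilterConfig(BaseModel):
    low_cut_hz: float = 0.2
    high_cut_hz: float = 5.0
    order: int = 4

    def to_spec(self) -> FilterSpec:
        return FilterSpec(self.low_cut_hz, self.high_cut_hz, self.order)


class SegmentationConfig(BaseModel):
    prominence_frac: float = 0.25
    min_sep_frac: float = 0.5
    duration_bounds_frac: Tuple[float, float] = (0.5, 2.0)


class LearningCurveConfig(BaseModel):
    initial: float
    asymptote: float
    tau: float = 2.5

    def to_curve(self) -> LearningCurve:
        return LearningCurve(self.initial, self.asymptote, self.tau)


class GroupSimConfig(BaseModel):
    magnitude: LearningCurveConfig
    shape: LearningCurveConfig
    drift_amp_mm: float = 0.3
    drift_freq_hz: float = 0.05
    noise_amp_mm: float = 0.1
    noise_band_hz: Tuple[float, float] = (10.0, 30.0)
    participant_sd: float = 0.25

    def to_params(self) -> SimulationParams:
        return SimulationParams(
            magnitude=self.magnitude.to_curve(),
            shape=self.shape.to_curve(),
            drift_amp_mm=self.drift_amp_mm,
            drift_freq_hz=self.drift_freq_hz,
            noise_amp_mm=self.noise_amp_mm,
            noise_band_hz=self.noise_band_hz,
            participant_sd=self.participant_sd,
        )

    @classmethod
    def from_params(cls, p: SimulationParams) -> "GroupSimConfig":
        return cls(
            magnitude=LearningCurveConfig(
                initial=p.magnitude.initial, asymptote=p.magnitude.asymptote, tau=p.magnitude.tau
            ),
            shape=LearningCurveConfig(
                initial=p.shape.initial, asymptote=p.shape.asymptote, tau=p.shape.tau
            ),
            drift_amp_mm=p.drift_amp_mm,
            drift_freq_hz=p.drift_freq_hz,
            noise_amp_mm=p.noise_amp_mm,
            noise_band_hz=p.noise_band_hz,
            participant_sd=p.participant_sd,
        )


def _default_groups() -> Dict[str, GroupSimConfig]:
    return {g: GroupSimConfig.from_params(p) for g, p in default_params_by_group().items()}


class RunConfig(BaseModel):
    """All pipeline parameters; defaults are the study constants."""

    seed: int = 0
    sampling_rate_hz: float = 80.3
    amplitude_mm: float = 4.0
    frequency_hz: float = 1.0
    target_mm: float = 4.0
    n_resample: int = 50
    alpha: float = 0.05
    trial_duration_s: float = 20.0
    n_per_group: Dict[str, int] = Field(
        default_factory=lambda: {"concurrent_vf": 10, "post_trial_vf": 11}
    )
    session2_pre_carryover: float = 0.0
    magnitude_method: str = "peak_to_trough"
    interp: str = "linear"
    filter: FilterConfig = Field(default_factory=FilterConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    simulation: Dict[str, GroupSimConfig] = Field(default_factory=_default_groups)

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_resample < 4:
            raise ValueError("n_resample must be >= 4")
        for g in self.n_per_group:
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
        return self

    def design(self) -> StudyDesign:
        return StudyDesign(
            n_per_group=dict(self.n_per_group),
            trial_duration_s=self.trial_duration_s,
            sampling_rate_hz=self.sampling_rate_hz,
            amplitude_mm=self.amplitude_mm,
            frequency_hz=self.frequency_hz,
            session2_pre_carryover=self.session2_pre_carryover,
        )

    def params_by_group(self) -> Dict[str, SimulationParams]:
        return {g: c.to_params() for g, c in self.simulation.items()}

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})
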