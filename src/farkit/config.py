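"""Validated run configuration and provenance logging.

Every tunable parameter of the pipeline lives in one document with defaults
equal to the clinical protocol where one exists: 3 frames x 100 s, 8x8
binning (938 um processed pitch), Gaussian sigma of 3 binned pixels, 1 mm
hotspot diameter, 1 MBq ROC increment, 95% confidence level, and a 60-180
min imaging-time window enforced as an exclusion rule.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = ["RunConfig", "ProvenanceLog", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised with the offending key path when a config fails validation."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AcquisitionConfig(_Strict):
    n_frames: int = Field(3, ge=1)
    frame_exposure_s: float = Field(100.0, gt=0)
    pixel_pitch_native_um: float = Field(117.25, gt=0)
    bin_factor: int = Field(8, ge=1)
    gain: float = Field(1e-4, gt=0)
    dark_offset: float = Field(0.0, ge=0)
    gamma_strike_rate: float = Field(2.0, ge=0)


class FluxConfig(_Strict):
    k_bg: float = Field(56.5, gt=0)
    k_t: float = Field(35.1, gt=0)
    lam_mm: float = Field(0.3, gt=0)
    d_max_mm: float = Field(1.0, gt=0)


class DetectionConfig(_Strict):
    threshold_k: float = Field(2.0, ge=0)
    min_diameter_mm: float = Field(1.0, gt=0)
    min_pixels: int = Field(1, ge=1)
    sigma_px: float = Field(3.0, gt=0)


class CohortConfig(_Strict):
    n_patients: int = Field(66, ge=1)
    activity_mean_mbq: float = 246.7
    activity_sd_mbq: float = Field(48.6, gt=0)
    activity_bounds_mbq: tuple[float, float] = (185.0, 334.0)
    time_mean_min: float = 143.9
    time_sd_min: float = Field(20.5, gt=0)
    time_bounds_min: tuple[float, float] = (60.0, 180.0)
    prevalence: float = Field(13 / 385, ge=0, le=1)
    step_threshold_mbq: float = 97.0
    step_width_mbq: float = Field(1.0, ge=0)


class StatsConfig(_Strict):
    ci_level: float = Field(0.95, gt=0, lt=1)
    roc_increment_mbq: float = Field(1.0, gt=0)
    roc_criterion: str = "lr"
    ppv_npv_method: str = "logit"


class RunConfig(_Strict):
    """Top-level validated configuration for :func:`farkit.pipeline.run_pipeline`."""

    seed: int = 0
    source: str = "synthetic"  # "synthetic" | "csv" | "reference"
    margins_csv: str | None = None
    imaging_time_window_min: tuple[float, float] = (60.0, 180.0)
    acquisition: AcquisitionConfig = Field(default_factory=AcquisitionConfig)
    flux: FluxConfig = Field(default_factory=FluxConfig)
    detection: DetectionConfig = Field(default_factory=DetectionConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        try:
            return cls.model_validate(data)
        except ValidationError as exc:
            locs = "; ".join(
                ".".join(str(p) for p in e["loc"]) + f": {e['msg']}" for e in exc.errors()
            )
            raise ConfigError(f"invalid configuration ({locs})") from exc


def load_config(path) -> RunConfig:
    """Load a YAML or JSON config file, rejecting unknown keys with their path."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfig.from_mapping(data or {})


class ProvenanceLog:
    """Config snapshot, seeds, version and per-stage record accounting.

    Every result bundle references exactly one provenance record; exclusions
    (out-of-window imaging times, unevaluable images) are counted here,
    never dropped silently.
    """

    def __init__(self, config: RunConfig):
        from . import __version__

        self.config_snapshot = config.model_dump()
        self.seed = config.seed
        self.version = __version__
        self.stages: list[dict] = []

    def record(self, stage: str, *, n_in: int, n_out: int, exclusions: dict | None = None):
        self.stages.append(
            {
                "stage": stage,
                "n_in": n_in,
                "n_out": n_out,
                "exclusions": exclusions or {},
            }
        )

    def as_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "config": self.config_snapshot,
            "stages": self.stages,
            "rounding": "percentages 1 d.p. half-up; CIs 2 d.p.",
        }
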