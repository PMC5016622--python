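"""Validated run configuration for the build→trace→fit→simulate→validate
pipeline.  A single YAML file (with CLI overrides) drives a whole run; every
seed is explicit so a manifest plus this config reproduces a run exactly."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator


class SiteConfig(BaseModel):
    latitude: float = 37.3
    longitude: float = 127.0
    utc_offset: float = 9.0
    north_offset: float = 0.0

    @field_validator("latitude")
    @classmethod
    def _lat(cls, v):
        if not -90 <= v <= 90:
            raise ValueError("latitude must lie in [-90, 90]")
        return v


class SceneConfig(BaseModel):
    rows: int = Field(1, ge=1)
    cols: int = Field(1, ge=1)
    spacing_m: float = Field(0.8, gt=0)
    build_seed: int = 0
    phyllotaxis_jitter_deg: float = Field(10.0, ge=0)
    structure_csv: str | None = None  # default: packaged paprika table


class OpticsConfig(BaseModel):
    reflectance: float = Field(0.10, ge=0)
    transmittance: float = Field(0.07, ge=0)

    @field_validator("transmittance")
    @classmethod
    def _sum(cls, v, info):
        rho = info.data.get("reflectance", 0.0)
        if rho + v > 1.0:
            raise ValueError("reflectance + transmittance must not exceed 1")
        return v


class TraceBudget(BaseModel):
    n_rays: int = Field(1_000_000, ge=1)
    max_impacts: int = Field(10, ge=1)
    seed: int = 0
    n_batches: int = Field(16, ge=1)


class FittingConfig(BaseModel):
    ci_low_pa: float = Field(30.0, gt=0)   # Rubisco window upper bound
    ci_high_pa: float = Field(40.0, gt=0)  # RuBP window lower bound
    respiration_rule: str = "table_coefficient"

    @field_validator("respiration_rule")
    @classmethod
    def _rule(cls, v):
        if v not in ("table_coefficient", "compensation_ratio"):
            raise ValueError("respiration_rule must be table_coefficient or "
                             "compensation_ratio")
        return v


class ChamberConfig(BaseModel):
    width: float = Field(1.0, gt=0)
    depth: float = Field(1.0, gt=0)
    height: float = Field(2.0, gt=0)
    air_temperature_c: float = 25.0
    pressure_pa: float = Field(101325.0, gt=0)
    leak_rate: float = Field(0.25, ge=0)
    subtract_leak: bool = False


class RunConfig(BaseModel):
    """Top-level configuration; see the module docstring."""

    site: SiteConfig = SiteConfig()
    scene: SceneConfig = SceneConfig()
    optics: OpticsConfig = OpticsConfig()
    trace: TraceBudget = TraceBudget()
    fitting: FittingConfig = FittingConfig()
    chamber: ChamberConfig = ChamberConfig()
    ci_rule: str = "ratio:0.7"
    ca_pa: float = Field(150.0, gt=0)
    weather_csv: str | None = None
    curves_csv: str | None = None
    chamber_log_csv: str | None = None
    output_dir: str = "canophot_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
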