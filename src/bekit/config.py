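"""Study configuration: apparatus constants, thresholds and file references."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .pampa import PampaGeometry

__all__ = ["Thresholds", "GeometryConfig", "SamplingConfig", "StudyConfig", "load_study_config"]


class Thresholds(BaseModel):
    """Decision thresholds; defaults follow regulatory convention."""

    f1_max: float = 15.0
    f2_min: float = 50.0
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    qc_r2_min: float = Field(default=0.95, ge=0.0, le=1.0)

    @field_validator("f1_max", "f2_min")
    @classmethod
    def _non_negative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("thresholds must be non-negative")
        return v


class GeometryConfig(BaseModel):
    """PAMPA plate geometry, cm³ / cm²."""

    Vd: float = Field(default=0.18, gt=0)
    Vr: float = Field(default=0.18, gt=0)
    S: float = Field(default=0.266, gt=0)

    def to_geometry(self) -> PampaGeometry:
        return PampaGeometry(Vd=self.Vd, Vr=self.Vr, S=self.S)


class SamplingConfig(BaseModel):
    """Dissolution withdrawal scheme (paddle apparatus)."""

    vessel_volume_ml: float = Field(default=1000.0, gt=0)
    sample_volume_ml: float = Field(default=3.0, gt=0)
    replace_with_medium: bool = True
    apply_correction: bool = False

    @model_validator(mode="after")
    def _volumes(self) -> "SamplingConfig":
        if self.sample_volume_ml >= self.vessel_volume_ml:
            raise ValueError("sample volume must be smaller than vessel volume")
        return self


class StudyConfig(BaseModel):
    """Top-level configuration tying the pipeline stages together."""

    calibration_files: dict[str, str] = Field(default_factory=dict)
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    theoretical_max_ug_ml: float = Field(default=1.5, gt=0)
    thresholds: Thresholds = Field(default_factory=Thresholds)
    sampling: SamplingConfig = Field(default_factory=SamplingConfig)
    reference_formulation: str | None = None
    output_dir: str = "."
    seed: int = 0

    def resolve_calibration_files(self, base: Path | None = None) -> dict[str, Path]:
        """Resolve calibration file paths, erroring on missing files."""
        out: dict[str, Path] = {}
        for name, rel in self.calibration_files.items():
            p = Path(rel) if base is None else base / rel
            if not p.exists():
                raise FileNotFoundError(f"calibration file for '{name}' not found: {p}")
            out[name] = p
        return out


def load_study_config(path: str | Path) -> StudyConfig:
    """Load a StudyConfig from YAML (a JSON file also parses)."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return StudyConfig.model_validate(data)
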