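"""Pipeline configuration: YAML loading, validation and typed accessors.

The YAML layout is validated strictly (unknown keys rejected) against the
pydantic models below; a JSON-Schema rendering of the same contract ships
in ``evocquant/schema/config.schema.json`` for external tooling.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from evocquant.detection import DetectionParams
from evocquant.errors import ConfigurationError
from evocquant.simulate import CohortSimSpec, ImageSimSpec
from evocquant.stain import RUIFROK_DAB, RUIFROK_HEMATOXYLIN, StainVectorSet


class DetectionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    pixel_size_um: float = 0.5
    min_radius_um: float = 5.0
    max_radius_um: float = 10.0
    splitting_threshold: float = 0.15
    cell_expansion_um: float = 3.0
    dab_od_threshold: float = 0.15
    smoothing_sigma_um: float = 1.0
    h_od_threshold: float = 0.1


class StainConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    name: str = "h-dab-default"
    hematoxylin: list[float] = Field(default_factory=lambda: list(RUIFROK_HEMATOXYLIN))
    dab: list[float] = Field(default_factory=lambda: list(RUIFROK_DAB))
    residual: list[float] | None = None  # None: cross product of h and dab

    @field_validator("hematoxylin", "dab", "residual")
    @classmethod
    def _three_components(cls, v):
        if v is not None and len(v) != 3:
            raise ValueError("stain vectors need exactly 3 RGB components")
        return v


class StatisticsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    posthoc_method: str = "bonferroni_paired_t"
    sphericity_alpha: float = 0.05

    @field_validator("posthoc_method")
    @classmethod
    def _known_method(cls, v):
        if v not in ("bonferroni_paired_t", "tukey_hsd"):
            raise ValueError(f"unknown posthoc method {v!r}")
        return v


class TileSimConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    tile_px: list[int] = Field(default_factory=lambda: [512, 512])
    pixel_size_um: float = 0.5
    n_nuclei: int = 40
    radius_um_range: list[float] = Field(default_factory=lambda: [5.5, 9.5])
    positive_fraction: float = 0.5
    h_od_mean: float = 0.8
    h_od_sd: float = 0.05
    dab_od_pos_mean: float = 0.6
    dab_od_pos_sd: float = 0.08
    dab_od_neg_mean: float = 0.03
    noise_sd: float = 0.0
    min_separation_um: float = 25.0


class CohortSimConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_samples: int = 12
    days: list[int] = Field(default_factory=lambda: [0, 3, 7, 10])
    baseline_ocn_mean: float = 47595.2
    baseline_ocn_sd: float = 3617.6
    tumor_fraction_mean: float = 0.8533
    tumor_survival: list[float] | None = None
    stromal_survival: list[float] | None = None
    pi_curve: list[float] | None = None
    pi_sd: float = 6.0
    sample_effect_sd: float = 0.05


class SimulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    tile: TileSimConfig = Field(default_factory=TileSimConfig)
    cohort: CohortSimConfig = Field(default_factory=CohortSimConfig)


class PipelineConfig(BaseModel):
    """Top-level validated configuration of the whole pipeline."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    white_point: float = 255.0
    schedule: list[int] = Field(default_factory=lambda: [0, 3, 7, 10])
    detection: DetectionConfig = Field(default_factory=DetectionConfig)
    stains: StainConfig = Field(default_factory=StainConfig)
    statistics: StatisticsConfig = Field(default_factory=StatisticsConfig)
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)

    def detection_params(self) -> DetectionParams:
        return DetectionParams(**self.detection.model_dump())

    def stain_vectors(self) -> StainVectorSet:
        rows = [self.stains.hematoxylin, self.stains.dab,
                self.stains.residual or [0.0, 0.0, 0.0]]
        return StainVectorSet.from_rows(rows, name=self.stains.name)

    def tile_spec(self, seed: int | None = None, **overrides) -> ImageSimSpec:
        d = self.simulation.tile.model_dump()
        d["tile_px"] = tuple(d["tile_px"])
        d["radius_um_range"] = tuple(d["radius_um_range"])
        d.update(overrides)
        d["seed"] = self.seed if seed is None else seed
        return ImageSimSpec(**d)

    def cohort_spec(self, seed: int | None = None) -> CohortSimSpec:
        d = self.simulation.cohort.model_dump()
        d["days"] = tuple(d["days"])
        kwargs = {k: v for k, v in d.items() if v is not None}
        for key in ("tumor_survival", "stromal_survival", "pi_curve"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        kwargs["seed"] = self.seed if seed is None else seed
        return CohortSimSpec(**kwargs)

    def config_hash(self) -> str:
        canonical = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load and validate a YAML config; defaults when no path is given."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return PipelineConfig.model_validate(raw)
    except Exception as exc:  # pydantic ValidationError
        raise ConfigurationError(f"invalid config {path}: {exc}") from exc


def json_schema() -> dict:
    """The JSON-Schema contract of the YAML config."""
    return PipelineConfig.model_json_schema()


def shipped_schema() -> dict:
    """The schema document shipped with the package."""
    ref = resources.files("evocquant") / "schema" / "config.schema.json"
    return json.loads(ref.read_text())
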