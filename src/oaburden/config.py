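"""Run configuration: YAML-backed, validated with pydantic.

A run is described by one :class:`RunConfig`: where the four stratified
inputs come from (files, or the synthetic generators), which utility value
set to use, pain-model overrides, simulation size and seed, and the PSA
block.  ``RunConfig.from_yaml`` merges a config file with keyword
overrides; validation errors list every offending field.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class SyntheticConfig(BaseModel):
    """Parameters for the synthetic input generators."""

    model_config = ConfigDict(extra="forbid")

    total_population: int = Field(1_800_000, gt=0)
    age_decay: float = Field(0.85, gt=0)
    female_share: float = Field(0.51, ge=0, le=1)
    maori_share: float = Field(0.11, ge=0, le=1)
    gompertz_shape: float = Field(0.09, gt=0)
    gompertz_levels: Optional[dict[str, float]] = None  # "ethnicity,sex" -> level
    closure_age: int = Field(110, ge=85)
    prevalence_base: Optional[float] = Field(None, ge=0, le=1)  # None -> packaged fixture
    prevalence_slope: float = Field(1.45, ge=0)
    pain_floor: float = Field(0.25, ge=0, le=1)
    pain_ceiling: float = Field(0.65, ge=0, le=1)
    pain_midpoint_age: float = 62.0
    pain_scale: float = Field(10.0, gt=0)
    moderate_share: float = Field(0.90, ge=0, le=1)

    def level_map(self) -> Optional[dict[tuple[str, str], float]]:
        if self.gompertz_levels is None:
            return None
        out = {}
        for key, v in self.gompertz_levels.items():
            eth, sex = (p.strip() for p in key.split(","))
            out[(eth, sex)] = float(v)
        return out


class InputPaths(BaseModel):
    """File-based inputs; any path left unset falls back to synthetic/fixture."""

    model_config = ConfigDict(extra="forbid")

    synthetic: bool = True
    life_table: Optional[Path] = None
    population: Optional[Path] = None
    prevalence: Optional[Path] = None
    pain_curve: Optional[Path] = None
    utilities: Optional[Path] = None

    @model_validator(mode="after")
    def _paths_or_synthetic(self) -> "InputPaths":
        if not self.synthetic:
            missing = [
                name
                for name in ("life_table", "population")
                if getattr(self, name) is None
            ]
            if missing:
                raise ValueError(
                    f"non-synthetic runs need explicit paths for: {', '.join(missing)}"
                )
        return self


class ValuationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    value_set: Literal["vas", "transformed"] = "vas"
    exponent: float = Field(1.61, gt=0)


class PainModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    init_mean: float = 30.0
    init_sd: float = Field(15.0, ge=0)
    annual_increment_mean: float = 0.5
    annual_increment_sd: float = Field(5.0, ge=0)


class SimulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_per_stratum: int = Field(2000, ge=1)


class PSABlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    run: bool = False
    n_draws: int = Field(500, ge=2)
    prior_low: float = Field(0.80, ge=0, le=1)
    prior_high: float = Field(1.00, ge=0, le=1)
    prevalence_mode: Literal["ppv_adjusted", "unadjusted", "sample_both"] = "ppv_adjusted"
    ppv: float = Field(0.9, gt=0, le=1)
    interval_level: float = Field(0.95, gt=0, lt=1)
    n_per_stratum: Optional[int] = Field(None, ge=1)


class RunConfig(BaseModel):
    """Top-level configuration for an end-to-end run."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    output_dir: Path = Path("oaburden_out")
    inputs: InputPaths = Field(default_factory=InputPaths)
    synthetic: SyntheticConfig = Field(default_factory=SyntheticConfig)
    valuation: ValuationConfig = Field(default_factory=ValuationConfig)
    pain_model: PainModelConfig = Field(default_factory=PainModelConfig)
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)
    psa: PSABlock = Field(default_factory=PSABlock)

    @classmethod
    def from_yaml(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        data: dict = {}
        if path is not None:
            with open(path, encoding="utf-8") as fh:
                data = yaml.safe_load(fh) or {}
        for key, value in overrides.items():
            if value is None:
                continue
            if "." in key:
                block, field_name = key.split(".", 1)
                data.setdefault(block, {})[field_name] = value
            else:
                data[key] = value
        return cls.model_validate(data)

    def config_hash(self) -> str:
        """Stable digest of the result-determining configuration.

        The output directory is excluded: where results are written does
        not change what they are.
        """
        payload = self.model_dump(mode="json")
        payload.pop("output_dir", None)
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()
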