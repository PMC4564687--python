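"""Run configuration: schema-validated settings for the analysis pipeline."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "GridConfig",
    "GridSearchConfig",
    "McConfig",
    "ModelFreeConfig",
    "SimulateConfig",
    "RunConfig",
    "load_config",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridConfig(_Strict):
    """Fixed τ array used when the grid search is disabled."""

    tau_min_ps: float = Field(21.0, gt=0)
    tau_max_ns: float = Field(21.0, gt=0)
    n: int = Field(6, ge=2)

    @model_validator(mode="after")
    def _ordered(self):
        if self.tau_min_ps * 1e-12 >= self.tau_max_ns * 1e-9:
            raise ValueError("tau_min must be smaller than tau_max")
        return self


class GridSearchConfig(_Strict):
    enabled: bool = False
    tau_min_ps_low: float = Field(1.0, gt=0)
    tau_min_ps_high: float = Field(100.0, gt=0)
    n_candidates: int = Field(13, ge=2)
    n_min: int = Field(4, ge=2)
    n_max: int = Field(9, ge=2)
    ratio: float = Field(1.0e3, gt=1)

    @model_validator(mode="after")
    def _ordered(self):
        if self.n_min > self.n_max:
            raise ValueError("n_min must be <= n_max")
        if self.tau_min_ps_low >= self.tau_min_ps_high:
            raise ValueError("tau_min_ps_low must be < tau_min_ps_high")
        return self


class McConfig(_Strict):
    steps: int = Field(510, ge=2)
    seed: int = Field(20150901, ge=0)


class ModelFreeConfig(_Strict):
    enabled: bool = True
    mode: Literal["2CT", "3CT", "auto"] = "auto"


class SimulateConfig(_Strict):
    """Synthetic-dataset settings (used by the `simulate` stage/command)."""

    n_res: int = Field(108, ge=1)
    first_residue: int = 146
    noise_scale: float = Field(1.0, ge=0)


class ConstantsConfig(_Strict):
    gamma_h: Optional[float] = None
    gamma_n: Optional[float] = None
    r_nh_angstrom: Optional[float] = None
    delta_sigma_ppm: Optional[float] = None
    theta_csa_deg: Optional[float] = None

    def overrides(self) -> dict:
        return {k: v for k, v in self.model_dump().items() if v is not None}


class RunConfig(_Strict):
    """Top-level pipeline configuration; unknown keys are rejected."""

    input_rates: Optional[str] = None  # None -> simulate a synthetic dataset
    fields_mhz: list[float] = Field(default_factory=lambda: [400.0, 500.0, 600.0, 800.0, 1000.0])
    j0_field_mhz: Optional[float] = None  # None -> highest field with usable eta pair
    residue_subset: Optional[list[int]] = None
    grid: GridConfig = Field(default_factory=GridConfig)
    gridsearch: GridSearchConfig = Field(default_factory=GridSearchConfig)
    mc: McConfig = Field(default_factory=McConfig)
    modelfree: ModelFreeConfig = Field(default_factory=ModelFreeConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    constants: ConstantsConfig = Field(default_factory=ConstantsConfig)
    output_dir: str = "impact_run"
    seed: int = Field(20150901, ge=0)
    log_level: Literal["DEBUG", "INFO", "WARNING", "ERROR"] = "INFO"
    render_barcode: bool = False

    def resolved_dict(self) -> dict:
        return json.loads(self.model_dump_json())


def load_config(path: Path | str) -> RunConfig:
    """Load a YAML or JSON run configuration file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig(**data)
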