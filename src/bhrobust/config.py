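"""Validated experiment configuration (YAML-backed, pydantic schema)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .dose import EngineParams
from .phantom import PhantomConfig
from .scenarios import UncertaintyModel

_ALL_STRATEGIES = ("proton3D-PS", "proton3D-BH", "proton4D-BH",
                   "photon3D-PS", "photon3D-BH", "photon4D-BH")


class PhantomSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    shape: tuple[int, int, int] = (64, 56, 48)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tumor_diameter_mm: float = 25.0
    tumor_center_mm: tuple[float, float, float] | None = None
    laterality: str = "left"
    noise_hu_sd: float = 0.0

    def to_phantom_config(self) -> PhantomConfig:
        return PhantomConfig(shape=self.shape, spacing=self.spacing,
                             tumor_diameter_mm=self.tumor_diameter_mm,
                             tumor_center_mm=self.tumor_center_mm,
                             laterality=self.laterality,
                             noise_hu_sd=self.noise_hu_sd)


class UncertaintySection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    Sigma_PS: tuple[float, float, float] = (1.1, 1.5, 1.4)
    sigma_PS: tuple[float, float, float] = (1.4, 1.7, 1.7)
    Sigma_BH_A: tuple[float, float, float] = (1.3, 1.2, 1.1)
    sigma_BH_A: tuple[float, float, float] = (0.9, 1.0, 1.0)
    Sigma_BH_B: tuple[float, float, float] = (1.0, 1.2, 2.2)
    sigma_BH_B: tuple[float, float, float] = (1.1, 1.6, 2.7)
    Sigma_SPR: float = 3.8

    def to_model(self) -> UncertaintyModel:
        return UncertaintyModel(**self.model_dump())


class EngineSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    photon_mu_per_mm: float = 0.0046
    photon_buildup_mm: float = 10.0
    penumbra_sigma_mm: float = 3.0
    proton_plateau: float = 0.4
    bragg_sigma_mm: float = 5.0
    distal_sigma_mm: float = 3.0
    lateral_sigma_mm: float = 5.0
    layer_spacing_mm: float = 4.0
    range_margin_mm: float = 6.0
    max_layers_per_subbeam: int = 10
    rbe_proton: float = 1.1
    mc_noise_sd: float = 0.0

    def to_params(self) -> EngineParams:
        return EngineParams(**self.model_dump())


class ExperimentConfig(BaseModel):
    """Everything needed for one end-to-end run; defaults reproduce the study
    error model and strategy table exactly."""

    model_config = ConfigDict(extra="forbid")
    phantom: PhantomSection = Field(default_factory=PhantomSection)
    uncertainty: UncertaintySection = Field(default_factory=UncertaintySection)
    engine: EngineSection = Field(default_factory=EngineSection)
    n_phantoms: int = 1
    strategies: list[str] = Field(default_factory=lambda: list(_ALL_STRATEGIES))
    eval_sets: list[str] = Field(default_factory=lambda: ["A", "B"])
    n_samples: int = 10000
    seed: int = 0
    output_dir: str | None = None

    @field_validator("strategies")
    @classmethod
    def _known_strategies(cls, v):
        for s in v:
            if s not in _ALL_STRATEGIES:
                raise ValueError(f"unknown strategy {s!r}")
        return v

    @field_validator("eval_sets")
    @classmethod
    def _known_sets(cls, v):
        for s in v:
            if s not in ("A", "B"):
                raise ValueError(f"unknown evaluation set {s!r} (use 'A'/'B')")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json"),
                                             sort_keys=False))
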