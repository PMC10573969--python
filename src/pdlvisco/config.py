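"""Validated configuration for the analysis pipeline (pydantic models).

Unknown keys are rejected everywhere so a typo in a YAML file fails loudly
instead of silently running defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .creep import FitContext
from .fiber import SegmentationParams
from .indentation import LoadProtocol


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolConfig(_Strict):
    loading_rate_mN_s: float = 0.5
    peak_load_mN: float = 3.0
    hold_time_s: float = 200.0
    indenter_radius_um: float = 100.0

    def build(self) -> LoadProtocol:
        return LoadProtocol(**self.model_dump())


class MaterialContextConfig(_Strict):
    """Fixed, non-identifiable constants of the creep fit."""

    Etf_MPa: float = 1.0
    Em_MPa: float = 1.0
    sigma0: float = 1.0
    g1: float = 1.0

    def build(self) -> FitContext:
        return FitContext(Etf=self.Etf_MPa, Em=self.Em_MPa, sigma0=self.sigma0, g1=self.g1)


class SegmentationConfig(_Strict):
    hue_lo: float = 0.45
    hue_hi: float = 0.75
    sat_min: float = 0.15

    def build(self) -> SegmentationParams:
        return SegmentationParams(**self.model_dump())


class SynthesisConfig(_Strict):
    noise_sd: float = 0.0
    thickness_um: float = 200.0
    image_size: int = Field(default=256, ge=8)
    n_points_per_region: int = Field(default=5, ge=1)
    n_slices: int = Field(default=5, ge=1)


class PipelineConfig(_Strict):
    """Full pipeline configuration."""

    seed: int = 0
    synthesize: bool = True
    input_dir: str | None = None
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    context: MaterialContextConfig = Field(default_factory=MaterialContextConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    synthesis: SynthesisConfig = Field(default_factory=SynthesisConfig)
    hold_relative_strain: bool = False
    unload_top_fraction: float = Field(default=0.5, gt=0, le=1)
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def config_hash(self) -> str:
        import hashlib
        import json

        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
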