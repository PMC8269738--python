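"""TOML pipeline configuration, validated with pydantic."""

from __future__ import annotations

import tomllib
from pathlib import Path

from pydantic import BaseModel, Field, ValidationError

from .errors import ConfigError

__all__ = ["PipelineConfig", "load_config"]


class SceneBlock(BaseModel):
    image_size: tuple[int, int] = (512, 512)
    px_per_cm: float = Field(10.0, gt=0)
    n_eggs: int = Field(3, ge=1)
    egg_axes_cm: tuple[float, float] = (3.3, 2.5)
    spot_fraction: float = Field(0.2, ge=0, lt=1)
    noise_sd: float = Field(0.004, ge=0)


class FadingBlock(BaseModel):
    slope_per_band: tuple[float, float, float, float] = (0.186, 0.186, 0.186, 0.089)
    cap: float = Field(0.95, gt=0, le=1)


class FilterBankBlock(BaseModel):
    scales: tuple[float, ...] = (16.0, 32.0, 64.0, 128.0)
    n_orientations: int = Field(5, ge=1)
    scale_factor: float = Field(1.0, gt=0)


class Exp1Block(BaseModel):
    days: tuple[int, ...] = (0, 3, 7)
    n_eggs: int = Field(10, ge=1)


class Exp2Block(BaseModel):
    days: tuple[int, ...] = (0, 7)
    n_nests: int = Field(7, ge=1)
    models: tuple[str, ...] = ("ferret", "human", "peafowl", "bluetit")
    k: int = Field(20, ge=2)
    max_fit_pixels: int = Field(20000, ge=100)


class PipelineConfig(BaseModel):
    seed: int = 0
    out_dir: Path = Path("results")
    scene: SceneBlock = Field(default_factory=SceneBlock)
    fading: FadingBlock = Field(default_factory=FadingBlock)
    filter_bank: FilterBankBlock = Field(default_factory=FilterBankBlock)
    exp1: Exp1Block = Field(default_factory=Exp1Block)
    exp2: Exp2Block = Field(default_factory=Exp2Block)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load and validate a TOML config; ``overrides`` patch top-level keys."""
    data: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    data.update(overrides)
    try:
        return PipelineConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
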