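"""Run configuration: schema-validated blocks for every pipeline stage.

A single global seed is expanded into independent substreams (layout
generation, spiking, layout rotations) so that, e.g., changing the
number of repeats does not perturb which layouts are generated.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator

from .evaluation import VARIANTS
from .model import _NONLINEARITIES
from .tomography import SmoothingParams, TomographyPlan

__all__ = ["RunConfig", "load_config", "spawn_rngs"]


class ModelBlock(BaseModel):
    variant: str = "default"
    n_subunits: int = Field(10, ge=1)
    nonlinearity: str = "rectified-linear"
    anchor: float = Field(30.0, gt=0)
    baseline: float = Field(0.0, ge=0)

    @field_validator("variant")
    @classmethod
    def _known_variant(cls, v):
        if v not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        return v

    @field_validator("nonlinearity")
    @classmethod
    def _known_nl(cls, v):
        if v not in _NONLINEARITIES:
            raise ValueError(f"nonlinearity must be one of {_NONLINEARITIES}")
        return v


class StimulusBlock(BaseModel):
    w: float = Field(5.0, gt=0)
    s: float = Field(2.5, ge=0)
    polarity: int = 1
    stripe_spacing: float | None = None

    @field_validator("polarity")
    @classmethod
    def _pol(cls, v):
        if v not in (-1, 1):
            raise ValueError("polarity must be +1 or -1")
        return v


class PlanBlock(BaseModel):
    n_angles: int = Field(36, ge=2)
    n_positions: int = Field(60, ge=2)
    position_step: float = Field(2.0 / 3.0, gt=0)
    repeats: int = Field(1, ge=1)
    response_mode: str = "spikes"

    @field_validator("response_mode")
    @classmethod
    def _mode(cls, v):
        if v not in ("rate", "spikes"):
            raise ValueError("response_mode must be 'rate' or 'spikes'")
        return v

    def to_plan(self) -> TomographyPlan:
        return TomographyPlan(
            angles=np.arange(self.n_angles) * (180.0 / self.n_angles),
            n_positions=self.n_positions,
            position_step=self.position_step,
            repeats=self.repeats,
            response_mode=self.response_mode,
        )


class SmoothingBlock(BaseModel):
    sigma_pos: float = Field(2.5, ge=0)  # % of arena size
    sigma_ang: float = Field(5.0, ge=0)  # degrees

    def to_params(self) -> SmoothingParams:
        return SmoothingParams(self.sigma_pos, self.sigma_ang)


class EvaluationBlock(BaseModel):
    threshold_frac: float = Field(0.3, ge=0, le=1)
    circle_frac: float = Field(0.9, gt=0, le=1)


class RunConfig(BaseModel):
    model: ModelBlock = Field(default_factory=ModelBlock)
    stimulus: StimulusBlock = Field(default_factory=StimulusBlock)
    plan: PlanBlock = Field(default_factory=PlanBlock)
    smoothing: SmoothingBlock = Field(default_factory=SmoothingBlock)
    evaluation: EvaluationBlock = Field(default_factory=EvaluationBlock)
    seed: int = 0
    arena_size: float = Field(40.0, gt=0)
    pixel_size_um: float = Field(7.5, gt=0)  # reporting only
    outdir: str = "."

    def dump_resolved(self, path) -> None:
        """Write the fully resolved config next to the run outputs."""
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))


def load_config(path) -> RunConfig:
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return RunConfig.model_validate(data or {})


def spawn_rngs(seed: int) -> dict[str, np.random.Generator]:
    """Independent substreams for layout, spiking and rotations."""
    children = np.random.SeedSequence(seed).spawn(3)
    return {
        "layout": np.random.default_rng(children[0]),
        "spiking": np.random.default_rng(children[1]),
        "rotation": np.random.default_rng(children[2]),
    }
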