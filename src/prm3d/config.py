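"""Run configuration: one validated document covering every pipeline stage."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator


class PhantomSection(BaseModel):
    n_copd: int = Field(40, ge=1)
    n_noncopd: int = Field(40, ge=1)
    seed: int = 0
    shape: tuple[int, int, int] = (64, 64, 64)
    upper_lobe_bias: float = Field(2.0, gt=0)


class PRMSection(BaseModel):
    insp_cut: float = -950.0
    exp_cut: float = -856.0

    @model_validator(mode="after")
    def _ordered(self):
        if self.insp_cut >= self.exp_cut:
            raise ValueError("insp_cut must be below exp_cut")
        return self


class TrainSection(BaseModel):
    input_kind: str = "prm"
    folds: int = Field(5, ge=2)
    iterations: int = Field(300, ge=1)
    batch_size: int = Field(25, ge=1)
    learning_rate: float = Field(1e-4, gt=0)
    seed: int = 0


class CamSection(BaseModel):
    n_examples: int = Field(2, ge=0)
    target_class: str = "copd"


class RunConfig(BaseModel):
    """Validated configuration for :func:`prm3d.pipeline.run_pipeline`."""

    out_dir: Path = Path("prm3d_run")
    phantom: PhantomSection = PhantomSection()
    prm: PRMSection = PRMSection()
    train: TrainSection = TrainSection()
    cam: CamSection = CamSection()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        doc = self.model_dump(mode="json")
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
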