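"""Pipeline configuration schema (validated; unknown keys rejected)."""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PathsConfig(_Strict):
    counts: str | None = None
    design: str | None = None
    annotation: str | None = None
    alignment: str | None = None
    clades: str | None = None  # reference leaf -> clade label TSV
    outdir: str = "results"


class ScreenSettings(_Strict):
    fdr_threshold: float = Field(0.01, gt=0)
    tpm_floor_high: float = Field(2.0, gt=0)
    tpm_ceiling_low: float = Field(2.0, gt=0)
    ratio_min: float = Field(1.5, gt=1)


class RnaiSettings(_Strict):
    fold_threshold: float = Field(1.5, gt=1)
    down_threshold: float | None = Field(None, gt=0, lt=1)  # default 1/fold
    mode: str = "ratio-of-means"


class ClusterSettings(_Strict):
    metric: str = "euclidean"
    linkage: str = "average"
    pseudocount: float = Field(0.1, ge=0)


class PhyloSettings(_Strict):
    bootstrap_reps: int = Field(1000, ge=1)


class SimulateSettings(_Strict):
    n_features: int = Field(2000, ge=1)
    dispersion: float = Field(0.05, ge=0)
    technical_dispersion: float = Field(0.005, ge=0)
    library_size_mean: float = Field(1e7, gt=0)
    library_size_cv: float = Field(0.25, ge=0)


class PipelineConfig(_Strict):
    paths: PathsConfig = Field(default_factory=PathsConfig)
    screen: ScreenSettings = Field(default_factory=ScreenSettings)
    rnai: RnaiSettings = Field(default_factory=RnaiSettings)
    cluster: ClusterSettings = Field(default_factory=ClusterSettings)
    phylo: PhyloSettings = Field(default_factory=PhyloSettings)
    simulate: SimulateSettings = Field(default_factory=SimulateSettings)
    seed: int = 0


def load_config(path=None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def dump_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=False)


def ensure_outdir(cfg: PipelineConfig) -> Path:
    out = Path(cfg.paths.outdir)
    if not out.parent.exists():
        raise FileNotFoundError(f"output directory parent missing: {out.parent}")
    out.mkdir(exist_ok=True)
    return out
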