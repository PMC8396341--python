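"""Structured pipeline configuration with lossless YAML round-trip.

Every default matches the module-level default it configures.  The
config hash (sha256 of the canonical YAML dump) is attached to log lines
so any artifact can be traced to the exact configuration that made it.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class SimulateConfig:
    n_slides: int = 8
    tiles_per_slide: int = 10
    width: int = 512
    height: int = 512
    max_cells: int | None = None


@dataclass
class TargetsConfig:
    sigma: float = 4.0
    side: int = 25
    d: float = 1.0
    normalize: bool = True


@dataclass
class ModelConfig:
    encoder_preset: str = "tiny"
    scse: bool = True
    upsample_mode: str = "bilinear"


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 8
    learning_rate: float = 1e-2
    scheduler_factor: float = 0.2
    scheduler_patience: int = 10
    checkpoint_every: int = 6


@dataclass
class DetectConfig:
    min_seed_separation: int = 8
    min_area: int = 0


@dataclass
class EvaluateConfig:
    match_threshold: float = 8.0
    cv_repeats: int = 4
    cv_folds: int = 5
    count_source: str = "detections"  # or "map_mass"


@dataclass
class QuantifyConfig:
    resolution_um_per_px: float = 0.5


@dataclass
class TdaConfig:
    discard_fraction: float = 0.1
    twonn_method: str = "linfit"
    metric: str = "cosine"
    embed_dim: int = 4
    n_neighbors: int = 25
    min_dist: float = 0.0
    min_cluster_size: int = 5
    min_samples: int = 16
    tiles_per_slide: int = 20


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "lymphoquant_out"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    targets: TargetsConfig = field(default_factory=TargetsConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)
    quantify: QuantifyConfig = field(default_factory=QuantifyConfig)
    tda: TdaConfig = field(default_factory=TdaConfig)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


_SECTIONS = {
    "simulate": SimulateConfig,
    "targets": TargetsConfig,
    "model": ModelConfig,
    "train": TrainConfig,
    "detect": DetectConfig,
    "evaluate": EvaluateConfig,
    "quantify": QuantifyConfig,
    "tda": TdaConfig,
}


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key, value in raw.items():
        if key in _SECTIONS:
            kwargs[key] = _SECTIONS[key](**(value or {}))
        elif key in ("seed", "output_dir"):
            kwargs[key] = value
        else:
            raise ValueError(f"unknown config section {key!r}")
    return PipelineConfig(**kwargs)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(config.to_yaml())
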