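"""Pipeline configuration, seed fan-out and provenance sidecars."""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .augment import AugmentationSpec
from .core import DEFAULT_CROP_SHAPE
from .network import NetworkSpec
from .quantify import QCConfig
from .synthetic import PhantomSpec
from .training import TrainConfig


class PipelineError(RuntimeError):
    """A stage cannot run; the message names what to run first."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global one (stage-name hashed),
    so stages are independently reproducible."""
    return (int(global_seed) * 0x9E3779B1 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    log_level: str = "INFO"
    n_female: int = 9
    n_male: int = 9
    desk_scale: bool = True
    crop_shape: Tuple[int, int, int] = DEFAULT_CROP_SHAPE
    cv_folds: int = 6
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    augmentation: AugmentationSpec = field(default_factory=AugmentationSpec)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    qc: QCConfig = field(default_factory=QCConfig)

    def __post_init__(self):
        if self.desk_scale:
            # shrink everything to CPU scale unless explicitly overridden
            if self.phantom == PhantomSpec():
                self.phantom = PhantomSpec.desk()
            if self.crop_shape == DEFAULT_CROP_SHAPE:
                self.crop_shape = (32, 32, 48)
            if self.network == NetworkSpec():
                self.network = NetworkSpec(width_multiplier=0.125, conv_kernel=3)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["network"] = self.network.to_dict()
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        sub = {
            "phantom": PhantomSpec,
            "augmentation": AugmentationSpec,
            "train": TrainConfig,
            "qc": QCConfig,
        }
        for key, klass in sub.items():
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in kwargs[key].items()
                })
        if "network" in kwargs and isinstance(kwargs["network"], dict):
            kwargs["network"] = NetworkSpec.from_dict(kwargs["network"])
        for key in ("crop_shape",):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        known = {f.name for f in fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)


def write_sidecar(artifact_path, stage: str, config: PipelineConfig) -> None:
    """Record provenance (config hash, seed, stage) next to an artifact."""
    side = Path(str(artifact_path) + ".provenance.json")
    side.write_text(json.dumps({
        "stage": stage,
        "seed": config.seed,
        "stage_seed": stage_seed(config.seed, stage),
        "config_hash": config.config_hash(),
        "package_version": __import__("psoasvol").__version__,
    }, indent=2))
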