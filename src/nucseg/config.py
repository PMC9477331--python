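"""Pipeline configuration: nested dataclasses with YAML round-trip.

A :class:`PipelineConfig` fully determines an end-to-end run — slide
synthesis, pseudo-label construction, mixup, network, training, evaluation —
from one global seed.  Every stage derives its own seed deterministically from
the global one (hash of stage name + seed), so stages are independently
reproducible.  Validation happens eagerly at construction: an inconsistent
config is rejected before any compute starts.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path
from typing import Tuple

import yaml

from .mixup import MixupConfig
from .network import NetworkConfig
from .training import TrainingConfig

__all__ = [
    "DataConfig",
    "PseudoLabelConfig",
    "PipelineConfig",
    "derive_seed",
]


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, fanned out from one seed."""
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


@dataclasses.dataclass
class DataConfig:
    """Synthetic study conditions: slide count, geometry and stain regime.

    Slides alternate high/low stain quality (index parity) to emulate the
    well- and weakly-stained acquisitions that motivate mixup augmentation.
    """

    n_train_slides: int = 20
    n_test_slides: int = 5
    slide_height: int = 256
    slide_width: int = 256
    n_nuclei: int = 50
    radius_min: float = 6.0
    radius_max: float = 12.0
    hue_jitter: float = 8.0
    noise_sd: float = 4.0
    overlap: float = 0.25

    def __post_init__(self) -> None:
        if self.n_train_slides < 1 or self.n_test_slides < 0:
            raise ValueError("need at least one training slide")
        if self.radius_min <= 0 or self.radius_min > self.radius_max:
            raise ValueError(
                f"need 0 < radius_min <= radius_max, got "
                f"({self.radius_min}, {self.radius_max})"
            )

    def quality_for(self, index: int) -> str:
        return "high" if index % 2 == 0 else "low"


@dataclasses.dataclass
class PseudoLabelConfig:
    """Sub-graph extraction and eligible-patch selection knobs."""

    subgraphs_per_slide: int = 3
    subgraph_size: int = 128
    label_size: int = 48
    min_frac: float = 0.05
    max_frac: float = 0.80
    max_patches: int = 210

    def __post_init__(self) -> None:
        if self.label_size % 2:
            raise ValueError(f"label_size must be even, got {self.label_size}")
        if self.subgraph_size < 2 * self.label_size:
            raise ValueError(
                f"subgraph_size {self.subgraph_size} must be >= 2*label_size "
                f"= {2 * self.label_size}"
            )
        if not 0.0 <= self.min_frac <= self.max_frac <= 1.0:
            raise ValueError(
                f"need 0 <= min_frac <= max_frac <= 1, got "
                f"({self.min_frac}, {self.max_frac})"
            )
        if self.max_patches < 3:
            raise ValueError("max_patches must allow a train/validation split")


def _default_network() -> NetworkConfig:
    # Desk-scale ladder: 3 levels, 8->16->32 channels.  The full-scale
    # configuration (depth 4, base 32) is available by overriding.
    return NetworkConfig(depth=3, base_channels=8, label_size=48)


def _default_training() -> TrainingConfig:
    return TrainingConfig(batch_size=16, learning_rate=1e-3, epoch_cap=30)


@dataclasses.dataclass
class PipelineConfig:
    data: DataConfig = dataclasses.field(default_factory=DataConfig)
    pseudo: PseudoLabelConfig = dataclasses.field(default_factory=PseudoLabelConfig)
    mixup: MixupConfig = dataclasses.field(default_factory=MixupConfig)
    network: NetworkConfig = dataclasses.field(default_factory=_default_network)
    training: TrainingConfig = dataclasses.field(default_factory=_default_training)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.network.label_size != self.pseudo.label_size:
            raise ValueError(
                f"network label_size {self.network.label_size} must match "
                f"pseudo-label size {self.pseudo.label_size}"
            )

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        kwargs = {}
        sections = {
            "data": DataConfig,
            "pseudo": PseudoLabelConfig,
            "mixup": MixupConfig,
            "network": NetworkConfig,
            "training": TrainingConfig,
        }
        for key, klass in sections.items():
            if key in payload:
                section = dict(payload.pop(key))
                if key == "mixup" and "lambda_range" in section:
                    section["lambda_range"] = tuple(section["lambda_range"])
                kwargs[key] = klass(**section)
        if "seed" in payload:
            kwargs["seed"] = int(payload.pop("seed"))
        if payload:
            raise ValueError(f"unknown config keys: {sorted(payload)}")
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        payload = self.to_dict()
        payload["mixup"]["lambda_range"] = list(payload["mixup"]["lambda_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls.from_dict(payload or {})
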