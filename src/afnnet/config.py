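"""Experiment configuration: one YAML document with model/loss/train/data sections.

Presets:

* ``bowl2018`` — 256×256 inputs, batch 8, 200 epochs, AdamW + cosine
  annealing (the protocol the architecture defaults to);
* ``monuseg`` — 224×224 inputs, batch 4, 300 epochs, plain Adam.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .errors import ConfigurationError
from .losses import LossWeights
from .model import ModelConfig
from .train import TrainConfig

__all__ = ["ExperimentConfig", "load_config", "PRESETS"]

PRESETS = {
    "bowl2018": {
        "train": {"optimizer": "adamw", "input_size": 256, "batch_size": 8,
                  "epochs": 200, "lr": 1e-3, "min_lr": 1e-5},
    },
    "monuseg": {
        "train": {"optimizer": "adam", "input_size": 224, "batch_size": 4,
                  "epochs": 300, "lr": 1e-3, "min_lr": 1e-5},
    },
}


class ExperimentConfig:
    """Materialized model/loss/train settings plus the raw data section."""

    def __init__(self, model: ModelConfig, train: TrainConfig, data: dict):
        self.model = model
        self.train = train
        self.data = data

    @classmethod
    def from_dict(cls, doc: dict) -> "ExperimentConfig":
        doc = dict(doc or {})
        model_d = dict(doc.get("model") or {})
        train_d = dict(doc.get("train") or {})
        loss_d = dict(doc.get("loss") or {})
        scheme = loss_d.pop("gradient_scheme", None)
        norm_d = loss_d.pop("normalize_distance", None)
        if loss_d:
            train_d["loss"] = LossWeights(**loss_d)
        if scheme is not None:
            train_d["gradient_scheme"] = scheme
        if norm_d is not None:
            train_d["normalize_distance"] = norm_d
        model = ModelConfig.from_dict({**ModelConfig().to_dict(), **model_d})
        train = TrainConfig.from_dict(train_d)
        return cls(model=model, train=train, data=dict(doc.get("data") or {}))

    def to_dict(self) -> dict:
        train_d = self.train.to_dict()
        loss_d = train_d.pop("loss")
        loss_d["gradient_scheme"] = train_d.pop("gradient_scheme")
        loss_d["normalize_distance"] = train_d.pop("normalize_distance")
        return {"model": self.model.to_dict(), "train": train_d,
                "loss": loss_d, "data": dict(self.data)}


def load_config(path=None, preset: str | None = None,
                overrides: dict | None = None) -> ExperimentConfig:
    """Merge (in increasing priority) defaults, a preset, a YAML file, overrides."""
    doc: dict = {}

    def merge(extra: dict):
        for section, values in (extra or {}).items():
            doc.setdefault(section, {})
            if not isinstance(values, dict):
                raise ConfigurationError(f"config section {section!r} must be a mapping")
            doc[section].update(values)

    if preset is not None:
        if preset not in PRESETS:
            raise ConfigurationError(
                f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
            )
        merge(PRESETS[preset])
    if path is not None:
        merge(yaml.safe_load(Path(path).read_text()) or {})
    if overrides:
        merge(overrides)
    return ExperimentConfig.from_dict(doc)
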