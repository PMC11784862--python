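"""Run configuration: a YAML file with model / train / augment blocks.

Every field defaults to the reference training recipe (16-frame clips,
batch 28, 45 epochs, Adam at 1e-4 with 0.1 step decay every 16 epochs,
weight decay 1e-4, ±25° rotation, flip/blur p=0.5, compression p=0.1), so a
run with no config file reproduces that recipe.  Unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .augment import AugmentConfig
from .model import ModelConfig
from .training import TrainConfig

_BLOCKS = {"model": ModelConfig, "train": TrainConfig, "augment": AugmentConfig}


@dataclass(frozen=True)
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0

    def with_seed(self, seed: int) -> "RunConfig":
        return RunConfig(
            model=dataclasses.replace(self.model, seed=seed),
            train=dataclasses.replace(self.train, seed=seed),
            augment=self.augment,
            seed=seed,
        )

    def describe(self) -> str:
        parts = [f"seed={self.seed}"]
        for name in ("model", "train", "augment"):
            block = getattr(self, name)
            fields = ", ".join(
                f"{f.name}={getattr(block, f.name)!r}" for f in dataclasses.fields(block)
            )
            parts.append(f"{name}({fields})")
        return " ".join(parts)


def _build_block(cls, values: dict, context: str):
    known = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(values) - set(known)
    if unknown:
        raise ValueError(f"unknown keys in '{context}' block: {sorted(unknown)}")
    coerced = {}
    for key, value in values.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    return cls(**coerced)


def load_run_config(path: str | Path | None = None, seed: int | None = None) -> RunConfig:
    """Parse a YAML run config; ``seed`` (when given) overrides every block's seed."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: run config must be a mapping")
    unknown = set(raw) - set(_BLOCKS) - {"seed"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    blocks = {
        name: _build_block(cls, raw.get(name, {}) or {}, name)
        for name, cls in _BLOCKS.items()
    }
    config = RunConfig(**blocks, seed=int(raw.get("seed", 0)))
    if "seed" in raw:
        # the file-level seed reaches every block that did not pin its own
        for name in ("model", "train"):
            if "seed" not in (raw.get(name) or {}):
                block = dataclasses.replace(getattr(config, name), seed=int(raw["seed"]))
                config = dataclasses.replace(config, **{name: block})
    if seed is not None:
        config = config.with_seed(seed)
    return config
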