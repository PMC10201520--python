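"""Run configuration: a YAML-serializable bundle of model + training settings.

Every artifact-producing command writes its fully-resolved configuration next
to its outputs, so any run can be reproduced from that file and its seed
alone.  Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .model import ModelConfig
from .training import TrainConfig


@dataclass
class RunConfig:
    """Everything a command needs: paths, architecture, optimization, seed."""

    corpus: str | None = None
    out_dir: str = "runs/latest"
    seed: int = 0
    backend: str = "gibbs"
    preset: str = "full"              # "full" | "reduced" | "continuous"
    model: dict = field(default_factory=dict)   # ModelConfig overrides
    train: dict = field(default_factory=dict)   # TrainConfig overrides
    n_molecules: int = 100            # fixture / generate default count
    train_fraction: float = 0.8
    n_runs: int = 100                 # reconstruct repetitions
    checkpoint: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    # ---- factories -------------------------------------------------------
    def model_config(self, vocab_size: int) -> ModelConfig:
        overrides = dict(self.model)
        if self.preset == "reduced":
            return ModelConfig.reduced(vocab_size, **overrides)
        if self.preset == "continuous":
            return ModelConfig.continuous(vocab_size, **overrides)
        if self.preset == "full":
            return ModelConfig(vocab_size=vocab_size, **overrides)
        raise ValueError(f"unknown preset {self.preset!r}")

    def train_config(self) -> TrainConfig:
        overrides = dict(self.train)
        overrides.setdefault("seed", self.seed)
        overrides.setdefault("backend", self.backend)
        if self.preset == "reduced":
            return TrainConfig.overfit(**overrides)
        return TrainConfig(**overrides)
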