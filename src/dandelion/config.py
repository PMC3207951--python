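"""Run configuration: the annealing constants and pipeline settings.

Defaults mirror the published run constants: initial temperature 10, final
temperature 0.001, 1000 proposals when training, 500 during interspecies
translation, confidence threshold 0.1.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclasses.dataclass
class RunConfig:
    t0: float = 10.0
    tn: float = 0.001
    maxfc_train: int = 1000
    maxfc_test: int = 500
    seed: int = 0
    variant: str = "exhaustive"
    threshold: float = 0.1
    condition_on_class: bool = False

    def __post_init__(self) -> None:
        if not (self.t0 > self.tn > 0):
            raise ValueError("need t0 > tn > 0")
        if self.maxfc_train < 1 or self.maxfc_test < 1:
            raise ValueError("iteration budgets must be >= 1")
        if self.variant not in ("naive", "exhaustive"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
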