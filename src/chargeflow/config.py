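"""Declarative run configuration.

A run is described by one YAML/JSON document: which model to use (inline or
by path), the initial excitation, the time grid, and the analysis options.
The same document is echoed into every output directory as a
reproducibility record; the physics pipeline itself is seed-free (the seed
only enters noise fixtures).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .constants import time_to_fs

__all__ = ["RunConfig"]

MIN_STEPS = 8


@dataclass
class RunConfig:
    model: dict | str | None = None          # inline model document or path to JSON
    fixture: str | None = None               # alternative to `model`
    embedding: str = "none"
    excitation: dict = field(
        default_factory=lambda: {"from": "HOMO", "to": "LUMO", "mode": "swap"}
    )
    dt: float = 1.0
    dt_unit: str = "as"
    duration: float = 25.0
    duration_unit: str = "fs"
    occupation_window: tuple = (20, 20)
    dipole_directions: dict = field(default_factory=dict)   # name -> 3-vector
    max_lag_fs: float | None = None
    spectrum_window: str | None = None
    zero_pad_factor: int = 4
    output_dir: str = "chargeflow_out"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def dt_fs(self) -> float:
        return time_to_fs(self.dt, self.dt_unit)

    @property
    def duration_fs(self) -> float:
        return time_to_fs(self.duration, self.duration_unit)

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_fs / self.dt_fs))

    def validate(self) -> None:
        if self.dt_fs <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < MIN_STEPS:
            raise ValueError(
                f"duration/dt yields {self.n_steps} steps; at least {MIN_STEPS} are required"
            )
        if self.model is None and self.fixture is None:
            raise ValueError("config must name either a model or a fixture")
        if isinstance(self.model, str) and not Path(self.model).exists():
            raise ValueError(f"model path {self.model!r} does not exist")
        mode = self.excitation.get("mode", "swap")
        if mode not in ("swap", "single", "none"):
            raise ValueError(f"unknown excitation mode {mode!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["occupation_window"] = list(self.occupation_window)
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "occupation_window" in d:
            d["occupation_window"] = tuple(d["occupation_window"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
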