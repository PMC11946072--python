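"""Run configuration: nested sections, strict YAML round-trip.

A `RunConfig` collects the simulation, model, training and output settings of
one run plus the single root seed everything derives from.  Unknown keys are
rejected on load so a typo cannot silently fall back to a default, and
`to_yaml`/`from_yaml` round-trip losslessly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dataset import SimConfig
from .model import ModelConfig
from .training import TrainConfig

__all__ = ["RunConfig"]


@dataclass
class OutputConfig:
    directory: str = "runs"
    save_montages: bool = True
    n_montage: int = 6


_SECTIONS = {
    "simulation": SimConfig,
    "model": ModelConfig,
    "training": TrainConfig,
    "output": OutputConfig,
}


def _build_section(cls, data: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in section {name!r}: {sorted(unknown)}")
    kwargs = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


@dataclass
class RunConfig:
    simulation: SimConfig = field(default_factory=SimConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    output: OutputConfig = field(default_factory=OutputConfig)
    root_seed: int = 0

    def to_dict(self) -> dict:
        d = {name: dataclasses.asdict(getattr(self, name)) for name in _SECTIONS}
        d["root_seed"] = self.root_seed
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - set(_SECTIONS) - {"root_seed"}
        if unknown:
            raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
        kwargs = {
            name: _build_section(sec_cls, data.get(name, {}) or {}, name)
            for name, sec_cls in _SECTIONS.items()
        }
        return cls(root_seed=int(data.get("root_seed", 0)), **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def apply_overrides(self, overrides: dict[str, str]) -> "RunConfig":
        """Apply dotted-key overrides like {"simulation.grid": "64"}."""
        data = self.to_dict()
        for dotted, raw in overrides.items():
            parts = dotted.split(".")
            node = data
            for p in parts[:-1]:
                if p not in node:
                    raise KeyError(f"unknown config path {dotted!r}")
                node = node[p]
            leaf = parts[-1]
            if leaf not in node:
                raise KeyError(f"unknown config path {dotted!r}")
            node[leaf] = yaml.safe_load(raw)
        return RunConfig.from_dict(data)
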