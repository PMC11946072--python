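"""Speckle/label dataset generation and the on-disk container.

`generate_dataset` runs the forward model end to end: draw a phase target,
synthesize the polarized input field, propagate it through the (possibly
drifting) scattering medium, record the camera frame.  Samples are organized
in contiguous *drift epochs*: the medium is frozen within an epoch and takes
one autoregressive drift step between epochs, emulating acquisition sessions
separated in time over a slowly changing tissue.

Container layout (single HDF5 file):

    speckle     (n, H, W)   float32 in [0, 1]   camera frames
    label       (n, C, H, W) float32 in [0, 1]  glyph labels, C in {1, 2}
    epoch       (n,) int32                      drift epoch per sample
    drift_step  (n,) int32                      medium drift counter
    medium_seed (n,) int32                      seed of the medium used
    attrs["config"]                             JSON of the full SimConfig

All datasets are written with ``track_times=False`` so identical runs produce
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from typing import Literal, Optional

import h5py
import numpy as np

from ._rng import child_seed
from .phase_encoding import PhaseTarget, generate_glyph, synthesize_input_field
from .scattering import (
    THICKNESS_LADDER,
    drift_medium,
    propagate,
    record_speckle,
    sample_dense_vtm,
    sample_layered_medium,
)

__all__ = ["SimConfig", "SpeckleDataset", "generate_dataset"]


@dataclass
class SimConfig:
    """Study conditions for one simulated acquisition run."""

    grid: int = 32
    medium: Literal["dense", "layered"] = "dense"
    coupling: float = 0.5
    ballistic_fraction: float = 0.3
    transmissivity: float = 0.9
    n_layers: int = 4
    layer_spacing: float = 8.0
    glyph_style: str = "digit-like"
    phase_scale: float = float(np.pi)
    basis: Literal["HV", "circular"] = "HV"
    polarization: Literal["vector", "scalar"] = "vector"
    mode: Literal["single", "dual"] = "single"
    n_epochs: int = 1
    drift_rate: float = 0.0
    noise: Optional[float] = None
    read_noise: float = 0.0
    speckle_blur: float = 0.0
    quantize: Optional[int] = 8
    thickness: Optional[str] = None  # key into THICKNESS_LADDER, overrides medium params

    def resolved(self) -> "SimConfig":
        if self.thickness is None:
            return self
        if self.thickness not in THICKNESS_LADDER:
            raise ValueError(
                f"unknown thickness {self.thickness!r}; choose from {sorted(THICKNESS_LADDER)}"
            )
        lvl = THICKNESS_LADDER[self.thickness]
        return dataclasses.replace(
            self,
            ballistic_fraction=lvl["ballistic_fraction"],
            transmissivity=lvl["transmissivity"],
            n_layers=lvl["n_layers"],
            speckle_blur=lvl["speckle_blur"],
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "SimConfig":
        return cls(**json.loads(s))


@dataclass
class SpeckleDataset:
    """In-memory dataset; `save`/`load` round-trip through HDF5."""

    speckle: np.ndarray  # (n, H, W) float32
    label: np.ndarray  # (n, C, H, W) float32
    epoch: np.ndarray  # (n,) int32
    drift_step: np.ndarray  # (n,) int32
    medium_seed: np.ndarray  # (n,) int32
    config: SimConfig

    def __len__(self) -> int:
        return self.speckle.shape[0]

    @property
    def n_label_channels(self) -> int:
        return self.label.shape[1]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            for name in ("speckle", "label", "epoch", "drift_step", "medium_seed"):
                f.create_dataset(name, data=getattr(self, name), track_times=False)
            f.attrs["config"] = self.config.to_json()

    @classmethod
    def load(cls, path) -> "SpeckleDataset":
        with h5py.File(path, "r") as f:
            missing = [k for k in ("speckle", "label") if k not in f]
            if missing:
                raise KeyError(f"container missing required array(s): {missing}")
            return cls(
                speckle=f["speckle"][:],
                label=f["label"][:],
                epoch=f["epoch"][:],
                drift_step=f["drift_step"][:],
                medium_seed=f["medium_seed"][:],
                config=SimConfig.from_json(f.attrs["config"]),
            )


def _sample_medium(cfg: SimConfig, seed: int):
    if cfg.medium == "dense":
        return sample_dense_vtm(
            cfg.grid,
            coupling=cfg.coupling,
            ballistic_fraction=cfg.ballistic_fraction,
            transmissivity=cfg.transmissivity,
            seed=seed,
        )
    if cfg.medium == "layered":
        return sample_layered_medium(
            cfg.grid,
            n_layers=cfg.n_layers,
            coupling=cfg.coupling,
            layer_spacing=cfg.layer_spacing,
            seed=seed,
        )
    raise ValueError(f"unknown medium kind {cfg.medium!r}")


def generate_dataset(config: SimConfig, n_samples: int, seed: int) -> SpeckleDataset:
    """Forward-model a full speckle/label dataset; deterministic given seed.

    Samples are split evenly into ``config.n_epochs`` contiguous drift epochs;
    the medium drifts by ``config.drift_rate`` between consecutive epochs.
    """
    cfg = config.resolved()
    if n_samples < cfg.n_epochs:
        raise ValueError("need at least one sample per epoch")
    if cfg.mode == "dual" and cfg.polarization == "scalar":
        warnings.warn(
            "dual targets with a scalar field: the field carries only delta1; "
            "the second label channel is unrecoverable from the speckle",
            stacklevel=2,
        )
    medium_seed = child_seed(seed, "medium")
    medium = _sample_medium(cfg, medium_seed)
    n_channels = 2 if cfg.mode == "dual" else 1

    speckle = np.empty((n_samples, cfg.grid, cfg.grid), dtype=np.float32)
    label = np.empty((n_samples, n_channels, cfg.grid, cfg.grid), dtype=np.float32)
    epoch_arr = np.empty(n_samples, dtype=np.int32)
    step_arr = np.empty(n_samples, dtype=np.int32)
    seed_arr = np.full(n_samples, medium_seed % (2**31 - 1), dtype=np.int32)

    bounds = np.linspace(0, n_samples, cfg.n_epochs + 1).astype(int)
    for e in range(cfg.n_epochs):
        if e > 0:
            medium = drift_medium(medium, cfg.drift_rate, seed=child_seed(seed, "drift-root"))
        for i in range(bounds[e], bounds[e + 1]):
            g1 = generate_glyph(cfg.glyph_style, cfg.grid, child_seed(seed, "glyph", i, 1))
            if cfg.mode == "dual":
                g2 = generate_glyph(cfg.glyph_style, cfg.grid, child_seed(seed, "glyph", i, 2))
                target = PhaseTarget(g1, g2, phase_scale=cfg.phase_scale, mode="dual")
            else:
                target = PhaseTarget(g1, phase_scale=cfg.phase_scale, mode="single")
            field = synthesize_input_field(target, basis=cfg.basis, polarization=cfg.polarization)
            out = propagate(field, medium)
            rec = record_speckle(
                out,
                noise=cfg.noise,
                read_noise=cfg.read_noise,
                speckle_blur=cfg.speckle_blur,
                quantize=cfg.quantize,
                seed=child_seed(seed, "camera", i),
                medium_seed=medium_seed,
                drift_step=medium.drift_step,
                encoding_mode=cfg.mode,
                polarization=cfg.polarization,
            )
            speckle[i] = rec.intensity.astype(np.float32)
            label[i] = target.labels().astype(np.float32)
            epoch_arr[i] = e
            step_arr[i] = medium.drift_step
    return SpeckleDataset(
        speckle=speckle,
        label=label,
        epoch=epoch_arr,
        drift_step=step_arr,
        medium_seed=seed_arr,
        config=cfg,
    )
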