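"""Hybrid dual-path speckle-restoration network.

Two parallel encoders process the speckle frame:

* a U-shaped convolutional path — four stages of (two 3x3 convolutions +
  2x2 max pooling) with channel doubling — captures local texture;
* a Transformer path — the image is cut into P x P patches, each patch is
  linearly projected to a K-dimensional token and given a learned positional
  embedding (X_embed = X * W_proj + pos_emb), then passed through stacked
  self-attention / feed-forward blocks — captures global structure, which
  matters for speckle because every output pixel depends on the whole input.

The two feature maps are fused at the bottleneck by elementwise
multiplication concatenated with both originals, mixed by a 1x1 convolution,
and decoded by a four-stage upsampling path with skip connections from the
convolutional encoder.  The head emits one channel (single-phase restoration,
SPIR) or two independent channels (dual-phase, DPIR) through a sigmoid, so
the output always matches the input's spatial size and lies in [0, 1].

``variant="cnn_baseline"`` removes the attention path and the fusion,
leaving the identical U-shaped network: the measured difference between the
variants isolates the contribution of global self-attention.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Literal

import numpy as np

from ._rng import rng_for
from .nn import Adam, Conv2d, Linear, Module, Parameter, Tensor, TransformerBlock, concat, no_grad

__all__ = ["ModelConfig", "RestorationModel", "build_model", "count_parameters",
           "save_checkpoint", "load_checkpoint"]

N_CNN_STAGES = 4  # fixed: four downsampling submodules


@dataclass
class ModelConfig:
    input_size: int = 256
    patch_size: int = 16
    embed_dim: int = 256
    n_attention_layers: int = 4
    n_heads: int = 8
    cnn_base_channels: int = 32
    output_channels: int = 1
    variant: Literal["trans_cnn", "cnn_baseline"] = "trans_cnn"

    def __post_init__(self) -> None:
        if self.input_size % self.patch_size:
            raise ValueError("input_size must be divisible by patch_size")
        if self.input_size % (2**N_CNN_STAGES):
            raise ValueError(f"input_size must be divisible by 2^{N_CNN_STAGES}")
        if self.output_channels not in (1, 2):
            raise ValueError("output_channels must be 1 (SPIR) or 2 (DPIR)")
        if self.variant not in ("trans_cnn", "cnn_baseline"):
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def n_tokens(self) -> int:
        return (self.input_size // self.patch_size) ** 2

    @classmethod
    def desk(cls, **overrides) -> "ModelConfig":
        """Small configuration that trains in minutes on one CPU core."""
        base = dict(
            input_size=32,
            patch_size=8,
            embed_dim=64,
            n_attention_layers=2,
            n_heads=4,
            cnn_base_channels=8,
        )
        base.update(overrides)
        return cls(**base)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        return cls(**json.loads(s))


class RestorationModel(Module):
    def __init__(self, config: ModelConfig, seed: int = 0):
        cfg = config
        self.config = cfg
        rng = rng_for(seed, "model-init")
        b = cfg.cnn_base_channels

        # convolutional encoder: channels b, 2b, 4b, 8b
        self.enc = []
        c_in = 1
        for s in range(N_CNN_STAGES):
            c_out = b * 2**s
            self.enc.append([Conv2d(c_in, c_out, 3, rng), Conv2d(c_out, c_out, 3, rng)])
            c_in = c_out
        c_bot = b * 2 ** (N_CNN_STAGES - 1)

        if cfg.variant == "trans_cnn":
            grid_tokens = cfg.input_size // cfg.patch_size
            self.patch_proj = Linear(cfg.patch_size**2, cfg.embed_dim, rng)
            self.pos_emb = Parameter(
                0.02 * rng.standard_normal((cfg.n_tokens, cfg.embed_dim)).astype(np.float32)
            )
            self.blocks = [
                TransformerBlock(cfg.embed_dim, cfg.n_heads, 2, rng)
                for _ in range(cfg.n_attention_layers)
            ]
            self.token_out = Linear(cfg.embed_dim, c_bot, rng)
            # align token grid to the bottleneck grid (input_size / 2^stages)
            bott = cfg.input_size // 2**N_CNN_STAGES
            if grid_tokens % bott and bott % grid_tokens:
                raise ValueError("token grid and bottleneck grid are incommensurate")
            self._token_grid = grid_tokens
            self._bottleneck_grid = bott
            self.fuse = Conv2d(3 * c_bot, c_bot, 1, rng)
        else:
            self.fuse = Conv2d(c_bot, c_bot, 1, rng)

        # decoder with skip connections from the convolutional encoder
        self.dec = []
        c_up = c_bot
        for s in reversed(range(N_CNN_STAGES)):
            c_skip = b * 2**s
            c_out = max(b, c_skip // 2) if s else b
            self.dec.append([Conv2d(c_up + c_skip, c_out, 3, rng), Conv2d(c_out, c_out, 3, rng)])
            c_up = c_out
        self.head = Conv2d(c_up, cfg.output_channels, 1, rng)

    # -- paths ---------------------------------------------------------------
    def _cnn_path(self, x: Tensor):
        skips = []
        for conv1, conv2 in self.enc:
            x = conv2(conv1(x).relu()).relu()
            skips.append(x)
            x = x.maxpool2x2()
        return x, skips

    def _transformer_path(self, x: Tensor) -> Tensor:
        cfg = self.config
        N = x.shape[0]
        P = cfg.patch_size
        g = self._token_grid
        # patchify: (N, 1, H, W) -> (N, T, P*P)
        tokens = (
            x.reshape(N, g, P, g, P)
            .transpose(0, 1, 3, 2, 4)
            .reshape(N, g * g, P * P)
        )
        t = self.patch_proj(tokens) + self.pos_emb
        for blk in self.blocks:
            t = blk(t)
        t = self.token_out(t)  # (N, T, c_bot)
        c = t.shape[-1]
        fmap = t.reshape(N, g, g, c).transpose(0, 3, 1, 2)
        while fmap.shape[-1] > self._bottleneck_grid:
            fmap = fmap.avgpool2x2()
        while fmap.shape[-1] < self._bottleneck_grid:
            fmap = fmap.upsample2x2()
        return fmap

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("expected a (N, 1, H, W) input batch")
        if x.shape[2] != self.config.input_size or x.shape[3] != self.config.input_size:
            raise ValueError(
                f"input spatial size {x.shape[2:]} does not match config "
                f"({self.config.input_size})"
            )
        f_cnn, skips = self._cnn_path(x)
        if self.config.variant == "trans_cnn":
            f_tr = self._transformer_path(x)
            fused = concat([f_cnn, f_tr, f_cnn * f_tr], axis=1)
        else:
            fused = f_cnn
        y = self.fuse(fused).relu()
        for (conv1, conv2), skip in zip(self.dec, reversed(skips)):
            y = y.upsample2x2()
            y = concat([y, skip], axis=1)
            y = conv2(conv1(y).relu()).relu()
        return self.head(y).sigmoid()

    def predict(self, batch: np.ndarray) -> np.ndarray:
        """Inference on a (N, H, W) or (N, 1, H, W) float array -> (N, C, H, W)."""
        arr = np.asarray(batch, dtype=np.float32)
        if arr.ndim == 3:
            arr = arr[:, None]
        with no_grad():
            return self(Tensor(arr)).data


def build_model(config: ModelConfig, seed: int = 0) -> RestorationModel:
    """Deterministically initialized restoration network."""
    return RestorationModel(config, seed=seed)


def count_parameters(model: RestorationModel) -> int:
    """Exact trainable-parameter count."""
    return model.n_parameters()


def save_checkpoint(model: RestorationModel, path, extra: dict | None = None) -> None:
    """Single-file archive: config JSON + named parameter tensors."""
    state = {f"param::{k}": v for k, v in model.state_dict().items()}
    meta = {"config": model.config.to_json(), "extra": json.dumps(extra or {})}
    np.savez(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path) -> tuple[RestorationModel, dict]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        config = ModelConfig.from_json(meta["config"])
        model = RestorationModel(config, seed=0)
        model.load_state_dict(
            {k[len("param::"):]: z[k] for k in z.files if k.startswith("param::")}
        )
        return model, json.loads(meta["extra"])
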