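"""The hybrid CNN + selective-SSM severity classifier.

A stack of convolutional blocks (conv 3x3 -> Mish -> batch-norm -> 2x2
max-pool -> dropout) halves the spatial grid per block while deepening the
channels; the final feature maps are flattened row-major into a sequence and
integrated by stacked Mamba blocks; mean pooling over time, dropout, and a
linear softmax head produce the five class probabilities.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .autograd import Tensor
from .functional import mish, softmax_np
from .layers import BatchNorm2d, Conv2d, Dropout, Linear, MaxPool2d, Module
from .mamba import MambaBlock
from .scan import DISCRETIZATION_MODES

CLASS_COUNT = 5


@dataclass
class ModelConfig:
    input_size: int = 128
    in_channels: int = 14
    cnn_channels: tuple[int, ...] = (32, 64, 128, 256)
    kernel: int = 3
    cnn_dropout: float = 0.1
    n_mamba_blocks: int = 4
    d_state: int = 16
    expand: int = 2
    d_conv: int = 4
    fc_dropout: float = 0.3
    n_classes: int = CLASS_COUNT
    discretization_mode: str = "as_printed"

    def __post_init__(self) -> None:
        if self.n_classes != CLASS_COUNT:
            raise ValueError("the classifier is defined over 5 classes")
        if self.discretization_mode not in DISCRETIZATION_MODES:
            raise ValueError(f"unknown discretization mode "
                             f"{self.discretization_mode!r}")
        if self.input_size % (2 ** len(self.cnn_channels)):
            raise ValueError("input_size must be divisible by 2^n_blocks")

    @property
    def grid(self) -> int:
        """Spatial grid side after the CNN stack."""
        return self.input_size // (2 ** len(self.cnn_channels))

    @property
    def seq_len(self) -> int:
        return self.grid * self.grid

    @classmethod
    def small(cls, in_channels: int = 14) -> "ModelConfig":
        """Reduced profile for CPU-scale experiments: 32x32 input, 3 conv
        blocks to a 4x4 grid, 2 Mamba blocks with an 8-dim state."""
        return cls(input_size=32, in_channels=in_channels,
                   cnn_channels=(16, 32, 64), n_mamba_blocks=2, d_state=8)


class ConvBlock(Module):
    """conv -> Mish -> batch-norm -> max-pool -> dropout, in that order."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 3, p_drop: float = 0.1):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, rng, k)
        self.bn = BatchNorm2d(c_out)
        self.pool = MaxPool2d()
        self.drop = Dropout(p_drop, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.drop(self.pool(self.bn(mish(self.conv(x)))))


def to_sequence(maps: Tensor) -> Tensor:
    """Row-major flatten of (B, C, G, G) feature maps to (B, G*G, C)."""
    B, C, H, W = maps.shape
    return maps.transpose((0, 2, 3, 1)).reshape(B, H * W, C)


class CNNMambaClassifier(Module):
    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        chans = (config.in_channels,) + tuple(config.cnn_channels)
        self.blocks = [ConvBlock(a, b, rng, config.kernel, config.cnn_dropout)
                       for a, b in zip(chans[:-1], chans[1:])]
        d_model = config.cnn_channels[-1]
        self.mamba = [MambaBlock(d_model, rng, config.d_state, config.expand,
                                 config.d_conv, config.discretization_mode)
                      for _ in range(config.n_mamba_blocks)]
        self.head_drop = Dropout(config.fc_dropout, rng)
        self.head = Linear(d_model, config.n_classes, rng)

    def forward(self, x: np.ndarray | Tensor) -> Tensor:
        """Logits for a batch of (B, C, S, S) feature tensors."""
        h = x if isinstance(x, Tensor) else Tensor(x)
        if h.shape[1] != self.config.in_channels or \
                h.shape[2] != self.config.input_size:
            raise ValueError(
                f"expected input (B, {self.config.in_channels}, "
                f"{self.config.input_size}, {self.config.input_size}), "
                f"got {tuple(h.shape)}")
        for blk in self.blocks:
            h = blk(h)
        seq = to_sequence(h)
        for mb in self.mamba:
            seq = mb(seq)
        pooled = seq.mean(axis=1)
        return self.head(self.head_drop(pooled))

    __call__ = forward

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class probabilities in eval mode (dropout off, running BN stats)."""
        was_training = self.training
        self.eval()
        out = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i:i + batch_size])
            out.append(softmax_np(logits.data))
        if was_training:
            self.train()
        return np.concatenate(out, axis=0)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        state = self.state_dict()
        running = {f"__bn{i}_mean": b.bn.running_mean
                   for i, b in enumerate(self.blocks)}
        running.update({f"__bn{i}_var": b.bn.running_var
                        for i, b in enumerate(self.blocks)})
        np.savez(path, **state, **running)
        cfg = asdict(self.config)
        path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "CNNMambaClassifier":
        path = Path(path)
        cfg = json.loads(path.with_suffix(".json").read_text())
        cfg["cnn_channels"] = tuple(cfg["cnn_channels"])
        model = cls(ModelConfig(**cfg))
        data = np.load(path if path.suffix == ".npz" else str(path) + ".npz")
        state = {k: data[k] for k in data.files if not k.startswith("__bn")}
        model.load_state_dict(state)
        for i, b in enumerate(model.blocks):
            b.bn.running_mean = data[f"__bn{i}_mean"]
            b.bn.running_var = data[f"__bn{i}_var"]
        return model
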