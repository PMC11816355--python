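"""1D residual encoder (ResNet-18 layout: 4 stages x 2 basic blocks)."""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm1d,
    Conv1d,
    Dense,
    Flatten,
    GlobalAvgPool,
    Layer,
    MaxPool1d,
    ReLU,
    Sequential,
)

__all__ = ["BasicBlock", "ResNet1d"]


class BasicBlock(Layer):
    """conv-BN-ReLU-conv-BN with identity (or 1x1 projection) shortcut."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.main = Sequential([
            Conv1d(c_in, c_out, kernel, stride, rng),
            BatchNorm1d(c_out),
            ReLU(),
            Conv1d(c_out, c_out, kernel, 1, rng),
            BatchNorm1d(c_out),
        ])
        self.project = None
        if stride != 1 or c_in != c_out:
            self.project = Sequential([
                Conv1d(c_in, c_out, 1, stride, rng),
                BatchNorm1d(c_out),
            ])
        self.relu = ReLU()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        main = self.main.forward(x, training)
        short = self.project.forward(x, training) if self.project else x
        return self.relu.forward(main + short, training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu.backward(dy)
        dx = self.main.backward(d)
        dx = dx + (self.project.backward(d) if self.project else d)
        return dx

    def walk(self) -> list[Layer]:
        out = self.main.walk()
        if self.project:
            out.extend(self.project.walk())
        return out


class ResNet1d(Layer):
    """Encoder: stem conv + pool, doubling-width residual stages, then a
    dense projection to the latent vector.

    ``stage_filters`` follows the standard convention of doubling the filter
    count each stage, e.g. (16, 32, 64, 128) for a base width of 16.  The
    readout either global-average-pools the final feature map (``pool="gap"``,
    input-length independent) or flattens it (``pool="flatten"``, preserving
    the spectral positions of features; requires ``input_len``).
    """

    def __init__(
        self,
        c_in: int,
        base_filters: int = 16,
        stages: int = 4,
        blocks_per_stage: int = 2,
        stem_kernel: int = 7,
        block_kernel: int = 3,
        latent_dim: int = 128,
        rng: np.random.Generator | None = None,
        pool: str = "flatten",
        input_len: int | None = None,
        stem_stride: int = 2,
    ) -> None:
        super().__init__()
        if latent_dim <= 0:
            raise ValueError("latent_dim must be positive")
        if stem_kernel % 2 == 0 or block_kernel % 2 == 0:
            raise ValueError("kernel sizes must be odd")
        rng = rng or np.random.default_rng(0)
        self.stage_filters = tuple(base_filters * 2**i for i in range(stages))
        layers: list[Layer] = [
            Conv1d(c_in, base_filters, stem_kernel, stem_stride, rng),
            BatchNorm1d(base_filters),
            ReLU(),
            MaxPool1d(3, 2),
        ]
        c_prev = base_filters
        for i, c in enumerate(self.stage_filters):
            for j in range(blocks_per_stage):
                stride = 2 if (i > 0 and j == 0) else 1
                layers.append(BasicBlock(c_prev, c, block_kernel, stride, rng))
                c_prev = c
        if pool == "gap":
            layers.extend([GlobalAvgPool(), Dense(c_prev, latent_dim, rng)])
        elif pool == "flatten":
            if input_len is None:
                raise ValueError("pool='flatten' requires input_len")
            out_len = input_len
            for stride in [stem_stride, 2] + [2] * (stages - 1):
                out_len = -(-out_len // stride)  # stem, pool, stages 2..n
            layers.extend([Flatten(), Dense(out_len * c_prev, latent_dim, rng)])
        else:
            raise ValueError("pool must be 'gap' or 'flatten'")
        layers.append(ReLU())
        self.net = Sequential(layers)
        self.latent_dim = latent_dim

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        return self.net.forward(x, training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(dy)

    def walk(self) -> list[Layer]:
        return self.net.walk()
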