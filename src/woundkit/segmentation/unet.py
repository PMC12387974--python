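"""U-Net encoder-decoder for wound and tissue segmentation.

The contracting path halves the spatial size per level with 2x2 max
pooling while doubling the filter count; the expanding path upsamples
back, concatenating same-level encoder features through skip
connections so full-resolution detail survives the bottleneck.  The
head emits per-pixel class scores at the input resolution.

This is a desk-scale network (default 128x128 inputs, 3 levels, 16 base
filters, ~0.5 M parameters) intended to be trainable on one CPU core in
minutes on the synthetic photo corpus — deliberately far smaller than
clinical-grade segmentation networks, but architecturally identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from ._nn import F32, Adam, Conv3x3, MaxPool2, ReLU, Upsample2, softmax

STAGE1_CLASSES = ("background", "wound")
STAGE2_CLASSES = ("other", "slough", "necrosis")


@dataclass
class SegConfig:
    """Architecture and training configuration for one U-Net stage."""

    input_size: Tuple[int, int] = (128, 128)
    in_channels: int = 3
    depth_levels: int = 3
    base_filters: int = 16
    classes: Tuple[str, ...] = STAGE1_CLASSES
    loss: str = "ce+dice"
    learning_rate: float = 1e-3
    batch_size: int = 8
    max_epochs: int = 30
    early_stop_patience: int = 10
    early_stop_min_delta: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_levels < 2:
            raise ValueError("depth_levels must be >= 2")
        h, w = self.input_size
        div = 2 ** self.depth_levels
        if h % div or w % div:
            raise ValueError(
                f"input size {self.input_size} not divisible by 2^"
                f"{self.depth_levels}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SegConfig":
        d = json.loads(text)
        d["input_size"] = tuple(d["input_size"])
        d["classes"] = tuple(d["classes"])
        return cls(**d)


def stage2_config(**kw) -> SegConfig:
    """Default stage-2 configuration: RGB masked to the wound plus the
    wound mask as a fourth channel; three tissue classes.

    Stage 2 operates on a wound-centred region of interest (the stage-1
    mask's bounding box, resampled to input_size), so its default input
    is smaller than stage 1's full frame."""
    kw.setdefault("in_channels", 4)
    kw.setdefault("classes", STAGE2_CLASSES)
    kw.setdefault("input_size", (64, 64))
    return SegConfig(**kw)


class UNet:
    """Plain-NumPy U-Net; built by :func:`build_unet`."""

    def __init__(self, config: SegConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        L, F = config.depth_levels, config.base_filters
        c_in = config.in_channels
        self.enc: List[List] = []
        ch = c_in
        for lvl in range(L):
            out = F * 2 ** lvl
            self.enc.append([Conv3x3(ch, out, rng), ReLU(),
                             Conv3x3(out, out, rng), ReLU()])
            ch = out
        self.pools = [MaxPool2() for _ in range(L)]
        bot = F * 2 ** L
        self.bottleneck = [Conv3x3(ch, bot, rng), ReLU(),
                           Conv3x3(bot, bot, rng), ReLU()]
        self.ups: List[Upsample2] = []
        self.dec: List[List] = []
        ch = bot
        for lvl in reversed(range(L)):
            out = F * 2 ** lvl
            self.ups.append(Upsample2())
            # conv after upsampling halves channels; concat doubles again
            self.dec.append([Conv3x3(ch, out, rng), ReLU(),
                             Conv3x3(2 * out, out, rng), ReLU(),
                             Conv3x3(out, out, rng), ReLU()])
            ch = out
        self.head = Conv3x3(ch, len(config.classes), rng)

    # ------------------------------------------------------------------
    def _layers(self):
        for block in self.enc:
            yield from block
        yield from self.bottleneck
        for block in self.dec:
            yield from block
        yield self.head

    @property
    def params(self):
        out = []
        for layer in self._layers():
            out.extend(layer.params)
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.params)

    # ------------------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """x: (N, C, H, W) float32 in [0, 1] -> logits (N, K, H, W)."""
        x = np.ascontiguousarray(x, dtype=F32)
        skips = []
        for block, pool in zip(self.enc, self.pools):
            for layer in block:
                x = layer.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        for layer in self.bottleneck:
            x = layer.forward(x, train)
        self._concat_ch = []
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            x = block[0].forward(x, train)   # channel-reducing conv
            x = block[1].forward(x, train)
            self._concat_ch.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            for layer in block[2:]:
                x = layer.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        L = len(self.dec)
        # dec[i] consumed encoder skip L-1-i in forward; collect skip grads
        dskips = [None] * L
        for i in range(L - 1, -1, -1):
            block = self.dec[i]
            for layer in reversed(block[2:]):
                d = layer.backward(d)
            ch = self._concat_ch[i]
            dskips[L - 1 - i] = d[:, :ch]
            d = np.ascontiguousarray(d[:, ch:])
            d = block[1].backward(d)
            d = block[0].backward(d)
            d = self.ups[i].backward(d)
        for layer in reversed(self.bottleneck):
            d = layer.backward(d)
        for lvl in range(L - 1, -1, -1):
            d = self.pools[lvl].backward(d)
            d = d + dskips[lvl]
            for layer in reversed(self.enc[lvl]):
                d = layer.backward(d)

    def predict(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Class probabilities (N, K, H, W) without storing activations."""
        outs = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i:i + batch_size], train=False)
            outs.append(softmax(logits))
        return np.concatenate(outs, axis=0)

    # -- checkpointing --------------------------------------------------
    def get_weights(self) -> List[np.ndarray]:
        return [p.copy() for p, _ in self.params]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for (p, _), w in zip(self.params, weights):
            p[...] = w

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        np.savez(os.path.join(directory, "weights.npz"),
                 *[p for p, _ in self.params])
        with open(os.path.join(directory, "config.json"), "w") as fh:
            fh.write(self.config.to_json())

    @classmethod
    def load(cls, directory: str) -> "UNet":
        with open(os.path.join(directory, "config.json")) as fh:
            config = SegConfig.from_json(fh.read())
        model = cls(config)
        data = np.load(os.path.join(directory, "weights.npz"))
        model.set_weights([data[k] for k in data.files])
        return model


def build_unet(config: SegConfig) -> UNet:
    """Construct an untrained U-Net for the given configuration."""
    return UNet(config)
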