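"""ResNet-18 binary classifier for single-channel slab images.

The architecture is the standard 18-layer residual network with two
modifications: a single input channel (SPECT slabs are one-channel images)
and a single output node whose sigmoid activation is the "probability of
Parkinson-typical reduction".  In fidelity mode (224x224 input, width
multiplier 1) the network has exactly 11,170,753 trainable parameters.

A desk mode (64x64 input, width multiplier 0.25) keeps the identical
topology at roughly 1/16 of the parameters so that full training runs
finish in minutes on one CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn

#: widths of the four residual stages at multiplier 1
BASE_WIDTHS = (64, 128, 256, 512)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Hyper-structure of the network; everything else is fixed topology."""

    input_size: int = 224
    input_channels: int = 1
    width_multiplier: float = 1.0
    blocks_per_stage: int = 2

    @property
    def widths(self) -> tuple[int, ...]:
        return tuple(max(1, round(w * self.width_multiplier)) for w in BASE_WIDTHS)

    @property
    def stem_width(self) -> int:
        return self.widths[0]


FIDELITY_SPEC = ArchitectureSpec(input_size=224, width_multiplier=1.0)
DESK_SPEC = ArchitectureSpec(input_size=64, width_multiplier=0.25)


class BasicBlock(nn.Module):
    """Two 3x3 convolutions with identity (or 1x1 projection) shortcut."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, stride=1, padding=1, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.relu2 = nn.ReLU()
        if stride != 1 or in_ch != out_ch:
            self.down_conv = nn.Conv2d(in_ch, out_ch, 1, stride=stride, rng=rng)
            self.down_bn = nn.BatchNorm2d(out_ch)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self.relu1.forward(self.bn1.forward(self.conv1.forward(x)))
        out = self.bn2.forward(self.conv2.forward(out))
        if self.down_conv is not None:
            identity = self.down_bn.forward(self.down_conv.forward(x))
        else:
            identity = x
        return self.relu2.forward(out + identity)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu2.backward(dy)
        dmain = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(d))))
        )
        if self.down_conv is not None:
            dskip = self.down_conv.backward(self.down_bn.backward(d))
        else:
            dskip = d
        return dmain + dskip


class ResNetSlab(nn.Module):
    """The full network.  ``forward`` returns logits; use :meth:`predict_proba`
    for sigmoid outputs in evaluation mode."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.spec = spec
        w = spec.widths
        self.stem_conv = nn.Conv2d(spec.input_channels, spec.stem_width, 7, stride=2, padding=3, rng=rng)
        self.stem_bn = nn.BatchNorm2d(spec.stem_width)
        self.stem_relu = nn.ReLU()
        self.pool = nn.MaxPool2d(3, 2, 1)
        self.stages: list[BasicBlock] = []
        in_ch = spec.stem_width
        for stage_idx, out_ch in enumerate(w):
            for block_idx in range(spec.blocks_per_stage):
                stride = 2 if (stage_idx > 0 and block_idx == 0) else 1
                self.stages.append(BasicBlock(in_ch, out_ch, stride, rng))
                in_ch = out_ch
        self.gap = nn.GlobalAvgPool()
        self.fc = nn.Linear(w[-1], 1, rng=rng)

    # -- inference/training passes ------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.spec.input_channels:
            raise ValueError(
                f"expected (B, {self.spec.input_channels}, H, W) input, got {x.shape}"
            )
        h = self.stem_relu.forward(self.stem_bn.forward(self.stem_conv.forward(x)))
        h = self.pool.forward(h)
        for block in self.stages:
            h = block.forward(h)
        h = self.gap.forward(h)
        return self.fc.forward(h)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.fc.backward(dlogits[:, None])
        d = self.gap.backward(d)
        for block in reversed(self.stages):
            d = block.backward(d)
        d = self.pool.backward(d)
        self.stem_conv.backward(self.stem_bn.backward(self.stem_relu.backward(d)))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid outputs with batch-norm in inference mode."""
        was_training = self.training
        self.set_training(False)
        try:
            probs = nn.sigmoid(self.forward(x))
        finally:
            self.set_training(was_training)
        return probs


def build_architecture(spec: ArchitectureSpec, seed: int = 0) -> ResNetSlab:
    """Instantiate the network with seeded He initialization."""
    return ResNetSlab(spec, seed=seed)


# -- parameter accounting ---------------------------------------------


@dataclass
class ParameterAccount:
    per_layer: list[tuple[str, int]] = field(default_factory=list)
    total: int = 0
    trainable: int = 0

    @property
    def param_bytes(self) -> int:
        """Storage at 4 bytes per float32 parameter."""
        return 4 * self.total

    def param_megabytes(self) -> float:
        return self.param_bytes / 1e6

    def input_megabytes(self, batch_size: int, input_size: int, channels: int = 1) -> float:
        return batch_size * channels * input_size * input_size * 4 / 1e6


def _block_params(in_ch: int, out_ch: int, downsample: bool) -> int:
    n = 9 * in_ch * out_ch + 9 * out_ch * out_ch  # two 3x3 convs, no bias
    n += 2 * 2 * out_ch  # two affine batch norms
    if downsample:
        n += in_ch * out_ch + 2 * out_ch  # 1x1 projection + its norm
    return n


def count_parameters(spec: ArchitectureSpec) -> ParameterAccount:
    """Closed-form per-layer parameter accounting for the topology.

    Cross-checked in the test suite against brute-force enumeration of an
    instantiated model.
    """
    acc = ParameterAccount()
    w = spec.widths
    stem = 49 * spec.input_channels * spec.stem_width
    acc.per_layer.append(("stem conv 7x7", stem))
    acc.per_layer.append(("stem batchnorm", 2 * spec.stem_width))
    in_ch = spec.stem_width
    for stage_idx, out_ch in enumerate(w):
        for block_idx in range(spec.blocks_per_stage):
            downsample = stage_idx > 0 and block_idx == 0
            n = _block_params(in_ch, out_ch, downsample)
            acc.per_layer.append(
                (f"stage{stage_idx + 1} block{block_idx + 1}", n)
            )
            in_ch = out_ch
    acc.per_layer.append(("fc 1-output", w[-1] + 1))
    acc.total = sum(n for _, n in acc.per_layer)
    acc.trainable = acc.total
    return acc


# -- preprocessing ----------------------------------------------------


def resize_bicubic(image: np.ndarray, target: int) -> np.ndarray:
    """Bicubic resize of a 2D image to target x target pixels."""
    if target <= 0:
        raise ValueError("target size must be positive")
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    if image.shape == (target, target):
        return image
    return _sk_resize(image, (target, target), order=3, mode="edge", anti_aliasing=False)
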