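"""Conditional GAN for 2.5D MR-to-CT slice translation.

The generator is a U-Net: a strided-convolution encoder, a residual
bottleneck, and a nearest-neighbour-upsampling decoder with skip
connections that concatenate encoder features into the decoder.  Its
input is a stack of adjacent axial MR slices treated as channels (the
2.5D setting) scaled to [-1, 1]; its output is the centre CT slice,
bounded to [-1, 1] by a final tanh.

The discriminator is five stride-2 convolution blocks with ReLU
activations followed by global average pooling and a sigmoid head that
scores a (MR stack, CT slice) pair as real or generated.

The training objective is the sum of an L1 term and a non-saturating
binary-cross-entropy adversarial term; a least-squares (LSGAN) variant
is available behind ``adv_mode``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nnet
from .nnet import (Conv2d, GlobalAvgPool, InstanceNorm, Linear, Param,
                   ReLU, Sequential, Sigmoid, Tanh, Upsample2)


@dataclass
class GeneratorSpec:
    """Architecture of the U-Net generator.

    ``depth`` down-samplings of factor 2 require the spatial extent to be
    divisible by ``2**depth``.  Channel width doubles per level from
    ``base_channels`` up to ``max_channels``.
    """

    in_slices: int = 3
    depth: int = 4
    base_channels: int = 12
    max_channels: int = 64
    n_residual_blocks: int = 2
    skip_connections: bool = True

    def __post_init__(self):
        if self.in_slices % 2 == 0:
            raise ValueError("in_slices must be odd (a centre slice plus context)")
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be >= 1")

    def channels(self) -> list[int]:
        return [min(self.base_channels * 2 ** i, self.max_channels)
                for i in range(self.depth + 1)]


@dataclass
class DiscriminatorSpec:
    """Five stride-2 conv blocks, ReLU activations, sigmoid scalar head.

    Deliberately light: with the study's 1:1 loss weighting, a large
    critic's gradient into the generator dwarfs the per-pixel L1
    gradient and the reconstruction converges slowly and erratically.
    """

    n_blocks: int = 5
    base_channels: int = 2
    max_channels: int = 16
    in_channels: int = 4  # conditional: MR stack + CT slice
    conditional: bool = True

    def channels(self) -> list[int]:
        return [min(self.base_channels * 2 ** i, self.max_channels)
                for i in range(self.n_blocks)]


@dataclass
class LossWeights:
    """Relative weights of the L1 and adversarial generator-loss terms."""

    lambda_l1: float = 1.0
    lambda_adv: float = 1.0
    adv_mode: str = "bce"  # "bce" (non-saturating) or "lsgan"

    def __post_init__(self):
        if self.lambda_l1 < 0 or self.lambda_adv < 0:
            raise ValueError("loss weights must be >= 0")
        if self.adv_mode not in ("bce", "lsgan"):
            raise ValueError("adv_mode must be 'bce' or 'lsgan'")


class _ResBlock(nnet.Layer):
    """conv-norm-relu-conv-norm with identity shortcut, ReLU after the add."""

    def __init__(self, c: int, rng: np.random.Generator):
        self.body = Sequential(
            Conv2d(c, c, 3, rng=rng), InstanceNorm(c), ReLU(),
            Conv2d(c, c, 3, rng=rng), InstanceNorm(c),
        )
        self.act = ReLU()

    def params(self):
        return self.body.params()

    def forward(self, x, train=True):
        return self.act.forward(x + self.body.forward(x, train), train)

    def backward(self, dy):
        d = self.act.backward(dy)
        return d + self.body.backward(d)


class UNetGenerator:
    """U-Net translator; callable on (N, H, W, in_slices) arrays in [-1, 1]."""

    def __init__(self, spec: GeneratorSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        ch = spec.channels()
        self.stem = Sequential(Conv2d(spec.in_slices, ch[0], 3, rng=rng),
                               InstanceNorm(ch[0]), ReLU())
        self.downs = [
            Sequential(Conv2d(ch[i], ch[i + 1], 4, stride=2, pad=1, rng=rng),
                       InstanceNorm(ch[i + 1]), ReLU())
            for i in range(spec.depth)
        ]
        self.bottleneck = Sequential(
            *[_ResBlock(ch[-1], rng) for _ in range(spec.n_residual_blocks)]
        )
        self.ups = []
        for i in range(spec.depth, 0, -1):
            cin = ch[i] + (ch[i - 1] if spec.skip_connections else 0)
            self.ups.append(Sequential(Upsample2(),
                                       Conv2d(cin, ch[i - 1], 3, rng=rng),
                                       InstanceNorm(ch[i - 1]), ReLU()))
        self.head = Sequential(Conv2d(ch[0], 1, 3, rng=rng), Tanh())
        self._modules = [self.stem, *self.downs, self.bottleneck, *self.ups, self.head]

    def params(self) -> list[Param]:
        return [p for m in self._modules for p in m.params()]

    def _check_extent(self, h: int, w: int) -> None:
        div = 2 ** self.spec.depth
        if h % div or w % div:
            raise ValueError(
                f"input extent {h}x{w} must be divisible by 2**depth = {div}; "
                f"pad to {-(-h // div) * div}x{-(-w // div) * div}"
            )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._check_extent(x.shape[1], x.shape[2])
        x = x.astype(nnet.F32, copy=False)
        feats = [self.stem.forward(x, train)]
        for down in self.downs:
            feats.append(down.forward(feats[-1], train))
        y = self.bottleneck.forward(feats[-1], train)
        skips = feats[:-1][::-1]
        self._skip_ch = []
        for up, skip in zip(self.ups, skips):
            if self.spec.skip_connections:
                # upsampled channels first, encoder skip second
                lay0 = up.layers[0]
                y = lay0.forward(y, train)
                self._skip_ch.append((y.shape[3], skip.shape[3]))
                y = np.concatenate([y, skip], axis=3)
                for lay in up.layers[1:]:
                    y = lay.forward(y, train)
            else:
                self._skip_ch.append(None)
                y = up.forward(y, train)
        return self.head.forward(y, train)

    def backward(self, dy: np.ndarray) -> None:
        dy = self.head.backward(dy)
        dskips = []
        for up, chans in zip(reversed(self.ups), reversed(self._skip_ch)):
            if chans is not None:
                cu, cs = chans
                for lay in reversed(up.layers[1:]):
                    dy = lay.backward(dy)
                dskips.append(dy[..., cu:cu + cs])
                dy = up.layers[0].backward(np.ascontiguousarray(dy[..., :cu]))
            else:
                dskips.append(None)
                dy = up.backward(dy)
        dy = self.bottleneck.backward(dy)
        dskips = dskips[::-1]  # dskips[depth-1-i] is the gradient w.r.t. feats[i]
        for i in range(len(self.downs) - 1, -1, -1):
            dy = self.downs[i].backward(dy)
            ds = dskips[len(self.downs) - 1 - i]
            if ds is not None:
                dy = dy + ds
        self.stem.backward(dy)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False)


class Discriminator:
    """Conditional real/fake classifier returning one probability per pair."""

    def __init__(self, spec: DiscriminatorSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        ch = spec.channels()
        layers: list[nnet.Layer] = []
        cin = spec.in_channels
        for c in ch:
            layers += [Conv2d(cin, c, 4, stride=2, pad=1, rng=rng), ReLU()]
            cin = c
        layers += [GlobalAvgPool(), Linear(cin, 1, rng=rng), Sigmoid()]
        self.net = Sequential(*layers)

    def params(self) -> list[Param]:
        return self.net.params()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h, w = x.shape[1], x.shape[2]
        div = 2 ** self.spec.n_blocks
        if h % div or w % div or h < div or w < div:
            raise ValueError(
                f"discriminator input extent {h}x{w} must be a multiple of "
                f"2**n_blocks = {div}"
            )
        p = self.net.forward(x, train)[:, 0]
        # float32 sigmoid saturates for extreme logits; keep the contract
        # that probabilities lie strictly inside (0, 1)
        return np.clip(p, 1e-7, 1.0 - 1e-7)

    def backward(self, dprob: np.ndarray) -> np.ndarray:
        return self.net.backward(dprob[:, None])

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, train=False)


def build_generator(spec: GeneratorSpec | None = None, seed: int = 0) -> UNetGenerator:
    """Seeded construction of the U-Net generator."""
    return UNetGenerator(spec or GeneratorSpec(), seed=seed)


def build_discriminator(spec: DiscriminatorSpec | None = None, seed: int = 0) -> Discriminator:
    """Seeded construction of the conditional discriminator."""
    return Discriminator(spec or DiscriminatorSpec(), seed=seed)


# ---------------------------------------------------------------------- #
# losses (scalar conventions; array probabilities are averaged)

_EPS = 1e-7


def _check_prob(p) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("discriminator probabilities must lie strictly in (0, 1)")
    return p


def generator_loss(pred: np.ndarray, target: np.ndarray,
                   disc_prob_on_fake, w: LossWeights | None = None) -> float:
    """L1 reconstruction plus adversarial term, each with its weight."""
    w = w or LossWeights()
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"pred {pred.shape} and target {target.shape} differ in shape")
    p = _check_prob(disc_prob_on_fake)
    l1 = np.mean(np.abs(pred - target))
    if w.adv_mode == "lsgan":
        adv = np.mean((p - 1.0) ** 2)
    else:
        adv = np.mean(-np.log(p))
    return float(w.lambda_l1 * l1 + w.lambda_adv * adv)


def discriminator_loss(prob_on_real, prob_on_fake, adv_mode: str = "bce") -> float:
    """Binary-cross-entropy (or least-squares) real/fake objective."""
    pr = _check_prob(prob_on_real)
    pf = _check_prob(prob_on_fake)
    if adv_mode == "lsgan":
        return float(np.mean((pr - 1.0) ** 2) + np.mean(pf ** 2))
    return float(np.mean(-np.log(pr)) + np.mean(-np.log(1.0 - pf)))
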