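"""Lightweight Ghost-style feature-extraction backbone.

The backbone follows the GhostNet family of efficient CNNs with two
modifications aimed at irregular lesion morphology:

* every spatial convolution inside the Ghost modules (and the stride-2
  downsampling step) is a *deformable* convolution whose sampling grid is
  displaced by learned, per-position offsets resolved with bilinear
  interpolation, and
* each bottleneck carries a decoupled fully-connected (DFC) attention branch
  that gates the Ghost-module output with a sigmoid map built from separate
  horizontal and vertical long-range aggregation stages.

A stem convolution (3x3, stride 2, batch-norm, ReLU) is followed by a stack
of bottlenecks and a final 1x1 expansion; global average pooling yields the
embedding shared by the classifier head and the retrieval gallery (960-d for
the full-size spec).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import BatchNorm2d, Conv2d, DeformConv2d, Module

__all__ = [
    "GhostModuleConfig", "DFCAttentionConfig", "BottleneckConfig", "BackboneSpec",
    "GhostModule", "DFCAttention", "Bottleneck", "Backbone",
    "toy_backbone_spec", "full_backbone_spec", "build_backbone", "extract_features",
    "ConvBranch", "BatchNormStats", "reparameterize",
    "save_weights", "load_weights",
]


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass
class GhostModuleConfig:
    """Channel arithmetic of a Ghost module: primary 1x1 path + cheap
    depthwise deformable 3x3 path, concatenated along channels."""
    cin: int
    primary_out: int
    secondary_out: int
    activation: str = "relu"  # "relu" | "none"

    def __post_init__(self):
        if self.primary_out < 1 or self.secondary_out < 1:
            raise ValueError("ghost module paths need at least one channel each")
        if self.secondary_out % self.primary_out:
            raise ValueError(
                "secondary (cheap, depthwise) channels must be a multiple of the "
                "primary channels")

    @property
    def cout(self) -> int:
        return self.primary_out + self.secondary_out

    @classmethod
    def split(cls, cin: int, cout: int, activation: str = "relu") -> "GhostModuleConfig":
        primary = math.ceil(cout / 2)
        return cls(cin, primary, cout - primary, activation)


@dataclass
class DFCAttentionConfig:
    pool: int = 2            # average-pool downsampling factor
    reduction: int = 8       # width divisor of the channel-mixing stage
    horizontal_kernel: int = 5
    vertical_kernel: int = 5
    upsample: str = "bilinear"

    def __post_init__(self):
        if self.reduction < 1:
            raise ValueError("reduction ratio must be >= 1")


@dataclass
class BottleneckConfig:
    cin: int
    expand: int
    cout: int
    stride: int = 1
    dfc: DFCAttentionConfig = field(default_factory=DFCAttentionConfig)

    def __post_init__(self):
        if self.stride not in (1, 2):
            raise ValueError("bottleneck stride must be 1 or 2")


@dataclass
class BackboneSpec:
    stem_channels: int
    blocks: list
    final_width: int = 960
    in_channels: int = 1
    offset_groups: int = 4

    @property
    def embedding_dim(self) -> int:
        # embedding dimension equals the final channel width by construction
        return self.final_width

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BackboneSpec":
        blocks = [
            BottleneckConfig(
                cin=b["cin"], expand=b["expand"], cout=b["cout"], stride=b["stride"],
                dfc=DFCAttentionConfig(**b.get("dfc", {})),
            )
            for b in d["blocks"]
        ]
        return cls(stem_channels=d["stem_channels"], blocks=blocks,
                   final_width=d["final_width"], in_channels=d.get("in_channels", 1),
                   offset_groups=d.get("offset_groups", 4))


def toy_backbone_spec(embedding_dim: int = 24) -> BackboneSpec:
    """Desk-scale two-bottleneck spec for tests and the synthetic study."""
    return BackboneSpec(
        stem_channels=8,
        blocks=[
            BottleneckConfig(cin=8, expand=16, cout=12, stride=2),
            BottleneckConfig(cin=12, expand=24, cout=16, stride=1),
        ],
        final_width=embedding_dim,
        in_channels=1,
        offset_groups=4,
    )


def full_backbone_spec() -> BackboneSpec:
    """Full-size spec following the published GhostNet width table, ending at
    960 channels / a 960-d embedding."""
    table = [  # (expand, cout, stride)
        (16, 16, 1), (48, 24, 2), (72, 24, 1), (72, 40, 2), (120, 40, 1),
        (240, 80, 2), (200, 80, 1), (184, 80, 1), (184, 80, 1), (480, 112, 1),
        (672, 112, 1), (672, 160, 2), (960, 160, 1), (960, 160, 1),
        (960, 160, 1), (960, 160, 1),
    ]
    blocks = []
    cin = 16
    for expand, cout, stride in table:
        blocks.append(BottleneckConfig(cin=cin, expand=expand, cout=cout, stride=stride))
        cin = cout
    return BackboneSpec(stem_channels=16, blocks=blocks, final_width=960,
                        in_channels=1, offset_groups=4)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

def _og(channels: int, offset_groups: int) -> int:
    # channels within an offset group share offsets; narrow maps fall back to
    # the largest divisor of the requested group count
    return math.gcd(channels, offset_groups)


class GhostModule(Module):
    """Primary 1x1 convolution plus a cheap depthwise deformable 3x3 path
    applied to the primary output; outputs are concatenated channel-wise."""

    def __init__(self, cfg: GhostModuleConfig, offset_groups: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        p = cfg.primary_out
        self.primary = Conv2d(cfg.cin, p, 1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(p)
        self.cheap = DeformConv2d(p, cfg.secondary_out, 3, padding=1, groups=p,
                                  offset_groups=_og(p, offset_groups), bias=False, rng=rng)
        self.bn2 = BatchNorm2d(cfg.secondary_out)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.cin:
            raise ValueError(f"expected {self.cfg.cin} input channels, got {x.shape[1]}")
        act = ad.relu if self.cfg.activation == "relu" else (lambda t: t)
        y1 = act(self.bn1(self.primary(x)))
        y2 = act(self.bn2(self.cheap(y1)))
        return ad.concat([y1, y2], axis=1)


class DFCAttention(Module):
    """Decoupled fully-connected attention.

    Pipeline: average-pool downsample -> 1x1 channel mixing (factorized
    through ``cout // reduction`` channels) -> horizontal depthwise 1xK stage
    -> vertical depthwise Kx1 stage -> sigmoid -> bilinear upsample back to
    the gated map's spatial size.  Output values lie in [0, 1].
    """

    def __init__(self, cin: int, cout: int, cfg: DFCAttentionConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.cout = cout
        hidden = max(cout // cfg.reduction, 1)
        self.squeeze = Conv2d(cin, hidden, 1, rng=rng)
        self.mix = Conv2d(hidden, cout, 1, rng=rng)
        kh, kv = cfg.horizontal_kernel, cfg.vertical_kernel
        self.horizontal = Conv2d(cout, cout, (1, kh), padding=(0, kh // 2),
                                 groups=cout, rng=rng)
        self.vertical = Conv2d(cout, cout, (kv, 1), padding=(kv // 2, 0),
                               groups=cout, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        a = ad.avg_pool2d(x, self.cfg.pool) if self.cfg.pool > 1 else x
        a = self.mix(self.squeeze(a))
        a = self.vertical(self.horizontal(a))
        a = ad.sigmoid(a)
        if a.shape[2:] != (h, w):
            a = ad.bilinear_resize(a, h, w)
        return a


class Bottleneck(Module):
    """Ghost bottleneck: expansion Ghost module gated by DFC attention, an
    optional stride-2 depthwise deformable downsampling, a projection Ghost
    module, and an additive shortcut."""

    def __init__(self, cfg: BottleneckConfig, offset_groups: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.ghost1 = GhostModule(GhostModuleConfig.split(cfg.cin, cfg.expand),
                                  offset_groups, rng)
        # attention runs in parallel on the block input and gates ghost1's output
        self.attention = DFCAttention(cfg.cin, cfg.expand, cfg.dfc, rng)
        if cfg.stride == 2:
            self.down = DeformConv2d(cfg.expand, cfg.expand, 3, stride=2, padding=1,
                                     groups=cfg.expand,
                                     offset_groups=_og(cfg.expand, offset_groups),
                                     bias=False, rng=rng)
            self.down_bn = BatchNorm2d(cfg.expand)
        self.ghost2 = GhostModule(GhostModuleConfig.split(cfg.expand, cfg.cout, "none"),
                                  offset_groups, rng)
        self.identity_shortcut = cfg.stride == 1 and cfg.cin == cfg.cout
        if not self.identity_shortcut:
            self.sc_dw = Conv2d(cfg.cin, cfg.cin, 3, stride=cfg.stride, padding=1,
                                groups=cfg.cin, bias=False, rng=rng)
            self.sc_dw_bn = BatchNorm2d(cfg.cin)
            self.sc_pw = Conv2d(cfg.cin, cfg.cout, 1, bias=False, rng=rng)
            self.sc_pw_bn = BatchNorm2d(cfg.cout)

    def shortcut(self, x: Tensor) -> Tensor:
        if self.identity_shortcut:
            return x
        return self.sc_pw_bn(self.sc_pw(self.sc_dw_bn(self.sc_dw(x))))

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.cin:
            raise ValueError(f"expected {self.cfg.cin} input channels, got {x.shape[1]}")
        f = self.ghost1(x) * self.attention(x)
        if self.cfg.stride == 2:
            f = self.down_bn(self.down(f))
        return self.ghost2(f) + self.shortcut(x)


class Backbone(Module):
    def __init__(self, spec: BackboneSpec, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.stem = Conv2d(spec.in_channels, spec.stem_channels, 3, stride=2,
                           padding=1, bias=False, rng=rng)
        self.stem_bn = BatchNorm2d(spec.stem_channels)
        self.blocks = [Bottleneck(b, spec.offset_groups, rng) for b in spec.blocks]
        last = spec.blocks[-1].cout if spec.blocks else spec.stem_channels
        self.head_conv = Conv2d(last, spec.final_width, 1, bias=False, rng=rng)
        self.head_bn = BatchNorm2d(spec.final_width)

    def forward_map(self, x: Tensor) -> Tensor:
        """Feature map before pooling."""
        if x.ndim != 4 or x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected input of shape (N, {self.spec.in_channels}, H, W), got {x.shape}")
        y = ad.relu(self.stem_bn(self.stem(x)))
        for block in self.blocks:
            y = block(y)
        return ad.relu(self.head_bn(self.head_conv(y)))

    def __call__(self, x: Tensor) -> Tensor:
        """Embeddings: global average pooling of the final feature map."""
        fmap = self.forward_map(x)
        return fmap.mean(axis=(2, 3))


def build_backbone(spec: BackboneSpec | None = None, seed: int = 0) -> Backbone:
    return Backbone(spec or full_backbone_spec(), seed=seed)


def extract_features(images: np.ndarray, backbone: Backbone,
                     batch_size: int = 32) -> np.ndarray:
    """Embed preprocessed images (N, H, W) or (N, 1, H, W) in eval mode."""
    x = np.asarray(images, dtype=np.float64)
    if x.ndim == 3:
        x = x[:, None]
    was_training = backbone.training
    backbone.eval()
    outs = []
    for lo in range(0, x.shape[0], batch_size):
        outs.append(backbone(Tensor(x[lo:lo + batch_size])).data)
    backbone.train(was_training)
    return np.concatenate(outs, axis=0)


# ---------------------------------------------------------------------------
# branch re-parameterization
# ---------------------------------------------------------------------------

@dataclass
class BatchNormStats:
    mean: np.ndarray
    var: np.ndarray
    scale: np.ndarray  # gamma
    shift: np.ndarray  # beta
    epsilon: float = 1e-5


@dataclass
class ConvBranch:
    weight: np.ndarray                 # (Cout, Cin_g, k, k)
    bias: np.ndarray | None = None     # (Cout,)
    bn: BatchNormStats | None = None


def _fold_bn(branch: ConvBranch) -> tuple[np.ndarray, np.ndarray]:
    w = np.asarray(branch.weight, dtype=np.float64)
    b = (np.zeros(w.shape[0]) if branch.bias is None
         else np.asarray(branch.bias, dtype=np.float64))
    if branch.bn is not None:
        s = np.asarray(branch.bn.scale, float) / np.sqrt(
            np.asarray(branch.bn.var, float) + branch.bn.epsilon)
        w = w * s[:, None, None, None]
        b = (b - np.asarray(branch.bn.mean, float)) * s + np.asarray(branch.bn.shift, float)
    return w, b


def reparameterize(branches: Sequence[ConvBranch],
                   target_k: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Merge parallel convolution branches into one equivalent kernel + bias.

    Each branch's frozen batch-norm is folded into its weights, kernels
    smaller than the target size are zero-padded to its center, and weights
    and biases are summed.  The merged convolution reproduces the sum of the
    branch outputs for every input.
    """
    if not branches:
        raise ValueError("need at least one branch")
    if target_k is None:
        target_k = max(b.weight.shape[2] for b in branches)
    merged_w = None
    merged_b = None
    for branch in branches:
        w, b = _fold_bn(branch)
        k = w.shape[2]
        if w.shape[2] != w.shape[3]:
            raise ValueError("re-parameterization expects square kernels")
        if k > target_k or (target_k - k) % 2:
            raise ValueError(
                f"branch kernel {k} cannot be centered inside target {target_k}")
        if k < target_k:
            pad = (target_k - k) // 2
            w = np.pad(w, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        if merged_w is None:
            merged_w, merged_b = w.copy(), b.copy()
        else:
            if w.shape != merged_w.shape:
                raise ValueError("branches disagree on channel geometry")
            merged_w += w
            merged_b += b
    return merged_w, merged_b


# ---------------------------------------------------------------------------
# weight persistence: array archive + JSON shape manifest
# ---------------------------------------------------------------------------

def save_weights(model: Module, path: str):
    state = model.named_state()
    np.savez(path, **state)
    manifest = {name: list(arr.shape) for name, arr in state.items()}
    with open(str(path) + ".manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def load_weights(model: Module, path: str):
    with np.load(path if str(path).endswith(".npz") else str(path) + ".npz") as archive:
        model.load_state({k: archive[k] for k in archive.files})
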