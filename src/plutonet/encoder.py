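"""Shared EfficientNetB0 feature extractor, truncated at the e5 tap.

The segmentation network only consumes the last three encoder scales — the
stride-8, stride-16 and stride-32 feature maps (e3, e4, e5).  Everything
beyond the e5 tap (the remaining stride-32 blocks, the 1x1 expansion and
the classifier) is never instantiated: those layers would contribute dead
parameters to the audit.

With the default configuration the instantiated trunk is the EfficientNetB0
stem plus blocks up to and including the first block of the sixth stage
(the first stride-32 block), giving taps with 40, 112 and 192 channels and
a trunk of 1,114,300 trainable parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import BatchNorm, Conv2d, Dense, DepthwiseConv2d, Module, Tensor


class ConfigurationError(ValueError):
    pass


# EfficientNetB0 stage table: (expand_ratio, kernel, stride, c_in, c_out, repeats)
_B0_STAGES = [
    (1, 3, 1, 32, 16, 1),
    (6, 3, 2, 16, 24, 2),
    (6, 5, 2, 24, 40, 2),
    (6, 3, 2, 40, 80, 3),
    (6, 5, 1, 80, 112, 3),
    (6, 5, 2, 112, 192, 4),
    (6, 3, 1, 192, 320, 1),
]

# ImageNet channel statistics used to normalise [0,1] inputs.
_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass(frozen=True)
class EncoderConfig:
    """Configuration of the truncated backbone.

    ``tap_stages`` are (stage, block) pairs whose outputs become e3/e4/e5;
    ``truncate_after`` must equal the last tap, so no layer beyond e5 exists.
    Defaults are the configuration pinned down by the published parameter
    audit: taps after stage-3 (stride 8, 40 ch), stage-5 (stride 16, 112 ch)
    and the first block of stage 6 (stride 32, 192 ch).
    """

    input_size: int = 224
    tap_stages: tuple = ((3, 2), (5, 3), (6, 1))
    truncate_after: tuple = (6, 1)
    pretrained: str | None = None
    width_mult: float = 1.0
    depth_mult: float = 1.0

    def validate(self) -> None:
        if self.input_size % 32 != 0:
            raise ConfigurationError("input_size must be divisible by 32")
        if list(self.tap_stages) != sorted(self.tap_stages):
            raise ConfigurationError("tap_stages must be ordered shallow to deep")
        if self.truncate_after != self.tap_stages[-1]:
            raise ConfigurationError(
                "truncate_after must coincide with the deepest tap "
                "(layers beyond e5 would be dead parameters)")


@dataclass
class FeatureMap:
    data: Tensor
    stride: int


@dataclass
class FeaturePyramid:
    e3: FeatureMap
    e4: FeatureMap
    e5: FeatureMap

    def __iter__(self):
        return iter((self.e3, self.e4, self.e5))


def _round_filters(f: float, width: float, divisor: int = 8) -> int:
    f *= width
    new = max(divisor, int(f + divisor / 2) // divisor * divisor)
    if new < 0.9 * f:
        new += divisor
    return int(new)


def _round_repeats(r: int, depth: float) -> int:
    return int(np.ceil(depth * r))


class _ConvBNAct(Module):
    def __init__(self, cin, cout, kernel, stride, rng, name):
        self.conv = Conv2d(cin, cout, kernel, stride, bias=False, rng=rng,
                           name=f"{name}_conv")
        self.bn = BatchNorm(cout, name=f"{name}_bn")
        self.name = name

    def __call__(self, x, training=False):
        return nn.silu(self.bn(self.conv(x), training))


class MBConv(Module):
    """Mobile inverted bottleneck with squeeze-excitation (the B0 block)."""

    def __init__(self, cin, cout, expand, kernel, stride, rng, name):
        self.name = name
        self.stride = stride
        self.has_skip = stride == 1 and cin == cout
        mid = cin * expand
        self.expand = None
        if expand != 1:
            self.expand = Conv2d(cin, mid, 1, bias=False, rng=rng,
                                 name=f"{name}_expand")
            self.expand_bn = BatchNorm(mid, name=f"{name}_expand_bn")
        self.dw = DepthwiseConv2d(mid, kernel, stride, rng=rng, name=f"{name}_dw")
        self.dw_bn = BatchNorm(mid, name=f"{name}_dw_bn")
        se_ch = max(1, int(cin * 0.25))
        self.se_reduce = Dense(mid, se_ch, rng=rng, name=f"{name}_se_reduce")
        self.se_expand = Dense(se_ch, mid, rng=rng, name=f"{name}_se_expand")
        self.project = Conv2d(mid, cout, 1, bias=False, rng=rng,
                              name=f"{name}_project")
        self.project_bn = BatchNorm(cout, name=f"{name}_project_bn")

    def __call__(self, x, training=False):
        h = x
        if self.expand is not None:
            h = nn.silu(self.expand_bn(self.expand(h), training))
        h = nn.silu(self.dw_bn(self.dw(h), training))
        z = nn.global_avg_pool(h)
        z = nn.sigmoid(self.se_expand(nn.silu(self.se_reduce(z))))
        gate = Tensor(z.data[:, None, None, :])
        gate._prev = (z,)
        gate._backward = lambda g: z._accum(g.sum(axis=(1, 2)))
        h = h * gate
        h = self.project_bn(self.project(h), training)
        if self.has_skip:
            h = h + x
        return h


class Encoder(Module):
    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        config.validate()
        self.config = config
        w, d = config.width_mult, config.depth_mult
        stem_ch = _round_filters(32, w)
        self.stem = _ConvBNAct(3, stem_ch, 3, 2, rng, "stem")
        self.blocks: list[MBConv] = []
        self._block_pos: list[tuple[int, int]] = []
        self._strides: list[int] = []
        stride = 2
        cin = stem_ch
        done = False
        for si, (e, k, s, _ci, co, r) in enumerate(_B0_STAGES, start=1):
            cout = _round_filters(co, w)
            for bi in range(1, _round_repeats(r, d) + 1):
                st = s if bi == 1 else 1
                self.blocks.append(MBConv(cin, cout, e, k, st, rng,
                                          f"block{si}{chr(ord('a') + bi - 1)}"))
                self._block_pos.append((si, bi))
                cin = cout
                if (si, bi) == config.truncate_after:
                    done = True
                    break
            if done:
                break
        if not done:
            raise ConfigurationError(f"truncate_after {config.truncate_after} "
                                     "not reached in the stage table")
        # per-block output strides
        self._strides = []
        stride = 2
        for (si, bi), blk in zip(self._block_pos, self.blocks):
            stride *= blk.stride
            self._strides.append(stride)
        tapset = set(config.tap_stages)
        missing = tapset - set(self._block_pos)
        if missing:
            raise ConfigurationError(f"tap blocks {missing} not instantiated")
        if config.pretrained:
            self.load_weights(config.pretrained)

    # -- weights -----------------------------------------------------------
    def load_weights(self, path: str) -> None:
        blob = np.load(path)
        for i, p in enumerate(self.params()):
            p.data = blob[f"p{i}"].astype(np.float32)

    def save_weights(self, path: str) -> None:
        np.savez(path, **{f"p{i}": p.data for i, p in enumerate(self.params())})

    # -- forward -----------------------------------------------------------
    def __call__(self, images: Tensor, training: bool = False) -> FeaturePyramid:
        n, h, w, c = images.data.shape
        size = self.config.input_size
        if (h, w, c) != (size, size, 3):
            raise ValueError(f"expected ({size},{size},3) images, got {(h, w, c)}")
        x = Tensor((images.data - _MEAN) / _STD)
        x._prev = (images,)
        x._backward = lambda g: images._accum(g / _STD)
        h_ = self.stem(x, training)
        taps = {}
        for pos, blk, st in zip(self._block_pos, self.blocks, self._strides):
            h_ = blk(h_, training)
            if pos in set(self.config.tap_stages):
                taps[pos] = FeatureMap(h_, st)
        t3, t4, t5 = (taps[p] for p in self.config.tap_stages)
        return FeaturePyramid(t3, t4, t5)

    @property
    def tap_channels(self) -> tuple[int, int, int]:
        chans = []
        for pos in self.config.tap_stages:
            idx = self._block_pos.index(pos)
            chans.append(self.blocks[idx].project.cout)
        return tuple(chans)

    @property
    def tap_strides(self) -> tuple[int, int, int]:
        return tuple(self._strides[self._block_pos.index(p)]
                     for p in self.config.tap_stages)


def build_encoder(config: EncoderConfig | None = None,
                  rng: np.random.Generator | None = None) -> Encoder:
    """Build the truncated backbone; raises ConfigurationError on bad config."""
    return Encoder(config or EncoderConfig(), rng or np.random.default_rng(0))


def extract_features(encoder: Encoder, images: np.ndarray | Tensor,
                     training: bool = False) -> FeaturePyramid:
    """Run the trunk on a batch of [0,1] RGB images (N,H,W,3)."""
    t = images if isinstance(images, Tensor) else Tensor(images)
    return encoder(t, training)
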