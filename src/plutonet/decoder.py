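"""Modified partial decoder: 64-filter reductions, full-scale concatenations,
asymmetric convolution blocks, squeeze-excitation, and the refinement head.

The decoder ignores the two shallowest encoder scales entirely (the partial-
decoder principle) and routes the three deep taps across scales:

    d1 <- se(acb(cat(r3(e3), r4(e4), r5a(e5))))          at stride 16
    d2 <- se(acb(cat(r3(e3), t(d1), r5b(e5))))           at stride 8
    d3 <- se(acb(cat(t(d1), t(d2), r5b(e5))))            at stride 4

where r* are 3x3 reduction convolutions to 64 channels (r3 and r5b are each
shared between their two uses), t are 3x3 transition convolutions on the
inter-decoder links, and every concatenand is bilinearly resized to the
stage resolution first.  A three-convolution refinement head carries d3 to
full resolution and a 1x1 convolution + sigmoid produces the main
prediction Pm.

The exact layer arrangement (reduction sharing, stage strides, transition
convolutions, head widths 164/76/174, squeeze-excitation bottleneck 14) is
the configuration pinned down by the published parameter and GMac audit;
see docs/methods.md for the derivation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .encoder import ConfigurationError, FeaturePyramid
from .nn import BatchNorm, Conv2d, Dense, Module, Tensor


@dataclass(frozen=True)
class DecoderConfig:
    reduction_filters: int = 64
    se_hidden: int = 14          # squeeze-excitation bottleneck width
    stage_strides: tuple = (16, 8, 4)
    head_widths: tuple = (164, 76, 174)
    head_strides: tuple = (4, 2, 1)
    head_channels: int = 1
    use_acb: bool = True         # asymmetric convolution blocks (else plain 3x3)
    use_se: bool = True

    def validate(self) -> None:
        if self.reduction_filters <= 0:
            raise ConfigurationError("reduction_filters must be positive")
        if self.se_hidden < 1:
            raise ConfigurationError("se bottleneck must be >= 1")
        if not (self.stage_strides[0] > self.stage_strides[1] > self.stage_strides[2]):
            raise ConfigurationError("stage_strides must be strictly decreasing")


class ReductionConv(Module):
    """Channel reduction to `filters` channels (conv(e) of the decoder
    equations): a 3x3 convolution + BN + ReLU, or — in the asymmetric
    configuration — the same with parallel 3x1 and 1x3 branches, each with
    its own full BN, summed before the ReLU."""

    def __init__(self, cin, filters, rng, name, use_acb=False):
        if filters <= 0:
            raise ConfigurationError("filters must be positive")
        self.conv = Conv2d(cin, filters, 3, bias=False, rng=rng, name=f"{name}_conv")
        self.bn = BatchNorm(filters, name=f"{name}_bn")
        self.c31 = self.c13 = None
        if use_acb:
            self.c31 = Conv2d(cin, filters, (3, 1), bias=False, rng=rng,
                              name=f"{name}_c31")
            self.b31 = BatchNorm(filters, name=f"{name}_b31")
            self.c13 = Conv2d(cin, filters, (1, 3), bias=False, rng=rng,
                              name=f"{name}_c13")
            self.b13 = BatchNorm(filters, name=f"{name}_b13")
        self.name = name

    def __call__(self, x, training=False):
        h = self.bn(self.conv(x), training)
        if self.c31 is not None:
            h = h + self.b31(self.c31(x), training) + self.b13(self.c13(x), training)
        return nn.relu(h)


class ACB(Module):
    """Asymmetric convolution block.

    Three parallel padded convolutions (3x3, 3x1, 1x3), each batch-normalised
    (shift-only BN on every branch), summed element-wise, then ReLU.  The
    square kernel carries the representation; the asymmetric branches
    strengthen it against aspect-ratio variation.
    """

    def __init__(self, cin, cout, rng, name):
        self.c33 = Conv2d(cin, cout, (3, 3), bias=False, rng=rng, name=f"{name}_c33")
        self.b33 = BatchNorm(cout, scale=False, name=f"{name}_b33")
        self.c31 = Conv2d(cin, cout, (3, 1), bias=False, rng=rng, name=f"{name}_c31")
        self.b31 = BatchNorm(cout, scale=False, name=f"{name}_b31")
        self.c13 = Conv2d(cin, cout, (1, 3), bias=False, rng=rng, name=f"{name}_c13")
        self.b13 = BatchNorm(cout, scale=False, name=f"{name}_b13")
        self.name = name

    def __call__(self, x, training=False):
        s = (self.b33(self.c33(x), training)
             + self.b31(self.c31(x), training)
             + self.b13(self.c13(x), training))
        return nn.relu(s)


class PlainBlock(Module):
    """The conventional block the ablation baseline uses in place of the ACB:
    one 3x3 convolution + shift-only BN + ReLU."""

    def __init__(self, cin, cout, rng, name):
        self.conv = Conv2d(cin, cout, 3, bias=False, rng=rng, name=f"{name}_conv")
        self.bn = BatchNorm(cout, scale=False, name=f"{name}_bn")
        self.name = name

    def __call__(self, x, training=False):
        return nn.relu(self.bn(self.conv(x), training))


class SEBlock(Module):
    """Squeeze-and-excitation channel recalibration.

    Global average pool -> bottleneck dense (ReLU) -> expansion dense
    (sigmoid) -> channel-wise rescale.  Both dense layers are biasless; the
    bottleneck width is an explicit count (default 14), the value the
    published parameter audit fixes.
    """

    def __init__(self, channels, hidden, rng, name):
        if hidden < 1:
            raise ConfigurationError("se bottleneck must be >= 1")
        self.reduce = Dense(channels, hidden, bias=False, rng=rng,
                            name=f"{name}_reduce")
        self.expand = Dense(hidden, channels, bias=False, rng=rng,
                            name=f"{name}_expand")
        self.name = name

    def excitation(self, x: Tensor) -> Tensor:
        z = nn.global_avg_pool(x)
        return nn.sigmoid(self.expand(nn.relu(self.reduce(z))))

    def __call__(self, x: Tensor, training=False) -> Tensor:
        z = self.excitation(x)
        gate = Tensor(z.data[:, None, None, :])
        gate._prev = (z,)
        gate._backward = lambda g: z._accum(g.sum(axis=(1, 2)))
        return x * gate


class TransitionConv(Module):
    """3x3 convolution + shift-only BN + ReLU on an inter-decoder link."""

    def __init__(self, channels, rng, name):
        self.conv = Conv2d(channels, channels, 3, bias=False, rng=rng,
                           name=f"{name}_conv")
        self.bn = BatchNorm(channels, scale=False, name=f"{name}_bn")
        self.name = name

    def __call__(self, x, training=False):
        return nn.relu(self.bn(self.conv(x), training))


class RefinementHead(Module):
    """Carries d3 to full resolution and produces the probability map.

    conv 3x3 (w1) at the d3 scale -> up x2 -> conv 3x3 (w2) -> up x2 ->
    conv 3x3 (w3) at full resolution -> 1x1 -> sigmoid.  Most of the
    network's computation lives here: fine-scale convolutions dominate the
    multiply-accumulate budget even though their parameter share is modest.
    """

    def __init__(self, cin, widths, rng, name="head"):
        w1, w2, w3 = widths
        self.c1 = Conv2d(cin, w1, 3, bias=False, rng=rng, name=f"{name}_c1")
        self.b1 = BatchNorm(w1, scale=False, name=f"{name}_b1")
        self.c2 = Conv2d(w1, w2, 3, bias=False, rng=rng, name=f"{name}_c2")
        self.b2 = BatchNorm(w2, scale=False, name=f"{name}_b2")
        self.c3 = Conv2d(w2, w3, 3, bias=False, rng=rng, name=f"{name}_c3")
        self.b3 = BatchNorm(w3, scale=False, name=f"{name}_b3")
        self.out = Conv2d(w3, 1, 1, bias=True, rng=rng, name=f"{name}_out")
        self.name = name

    def __call__(self, d3: Tensor, input_size: int, training=False) -> Tensor:
        h = nn.relu(self.b1(self.c1(d3), training))
        h = nn.resize_bilinear(h, (input_size // 2, input_size // 2))
        h = nn.relu(self.b2(self.c2(h), training))
        h = nn.resize_bilinear(h, (input_size, input_size))
        h = nn.relu(self.b3(self.c3(h), training))
        return nn.sigmoid(self.out(h))


def _to_scale(fm: Tensor, size: int) -> Tensor:
    return nn.resize_bilinear(fm, (size, size))


class ModifiedPartialDecoder(Module):
    """The full main-branch decoder over an encoder pyramid."""

    def __init__(self, tap_channels: tuple[int, int, int],
                 config: DecoderConfig, rng: np.random.Generator):
        config.validate()
        self.config = config
        c3, c4, c5 = tap_channels
        f = config.reduction_filters
        # reduction convolutions; r3 and r5b are each shared across two uses
        a = config.use_acb
        self.r3 = ReductionConv(c3, f, rng, "reduce_e3", use_acb=a)
        self.r4 = ReductionConv(c4, f, rng, "reduce_e4", use_acb=a)
        self.r5a = ReductionConv(c5, f, rng, "reduce_e5_d1", use_acb=a)
        self.r5b = ReductionConv(c5, f, rng, "reduce_e5_d23", use_acb=a)
        block = ACB if config.use_acb else PlainBlock
        self.stage1 = block(3 * f, f, rng, "d1")
        self.stage2 = block(3 * f, f, rng, "d2")
        self.stage3 = block(3 * f, f, rng, "d3")
        if config.use_se:
            self.se1 = SEBlock(f, config.se_hidden, rng, "d1_se")
            self.se2 = SEBlock(f, config.se_hidden, rng, "d2_se")
            self.se3 = SEBlock(f, config.se_hidden, rng, "d3_se")
        else:
            self.se1 = self.se2 = self.se3 = None
        self.t12 = TransitionConv(f, rng, "trans_d1_d2")
        self.t13 = TransitionConv(f, rng, "trans_d1_d3")
        self.t23 = TransitionConv(f, rng, "trans_d2_d3")
        self.head = RefinementHead(f, config.head_widths, rng)

    # -- pieces, exposed for testing and reuse -----------------------------
    def reduced_taps(self, pyramid: FeaturePyramid, training=False):
        """The 64-channel reduced taps (at their native scales)."""
        return (self.r3(pyramid.e3.data, training),
                self.r4(pyramid.e4.data, training),
                self.r5a(pyramid.e5.data, training))

    def __call__(self, pyramid: FeaturePyramid, input_size: int,
                 training=False) -> Tensor:
        s1, s2, s3 = (input_size // s for s in self.config.stage_strides)
        e3r = self.r3(pyramid.e3.data, training)
        e4r = self.r4(pyramid.e4.data, training)
        e5ra = self.r5a(pyramid.e5.data, training)
        e5rb = self.r5b(pyramid.e5.data, training)

        d1 = self.stage1(nn.concat([_to_scale(e3r, s1), _to_scale(e4r, s1),
                                    _to_scale(e5ra, s1)]), training)
        if self.se1 is not None:
            d1 = self.se1(d1, training)

        d1_up2 = self.t12(_to_scale(d1, s2), training)
        d2 = self.stage2(nn.concat([_to_scale(e3r, s2), d1_up2,
                                    _to_scale(e5rb, s2)]), training)
        if self.se2 is not None:
            d2 = self.se2(d2, training)

        d1_up3 = self.t13(_to_scale(d1, s3), training)
        d2_up3 = self.t23(_to_scale(d2, s3), training)
        d3 = self.stage3(nn.concat([d1_up3, d2_up3, _to_scale(e5rb, s3)]),
                         training)
        if self.se3 is not None:
            d3 = self.se3(d3, training)

        return self.head(d3, input_size, training)


# -- free functions mirroring the individual decoder operations -------------


def reduce_channels(fm: Tensor, filters: int,
                    rng: np.random.Generator | None = None,
                    layer: ReductionConv | None = None,
                    training: bool = False) -> Tensor:
    """Apply a 3x3 reduction to `filters` channels (spatial size preserved)."""
    if layer is None:
        cin = fm.data.shape[-1] if isinstance(fm, Tensor) else fm.shape[-1]
        layer = ReductionConv(cin, filters, rng or np.random.default_rng(0),
                              "reduce")
    t = fm if isinstance(fm, Tensor) else Tensor(fm)
    return layer(t, training)


def acb(fm: Tensor, rng: np.random.Generator | None = None,
        layer: ACB | None = None, training: bool = False) -> Tensor:
    if layer is None:
        cin = fm.data.shape[-1] if isinstance(fm, Tensor) else fm.shape[-1]
        layer = ACB(cin, cin, rng or np.random.default_rng(0), "acb")
    t = fm if isinstance(fm, Tensor) else Tensor(fm)
    return layer(t, training)


def se_block(fm: Tensor, ratio_hidden: int,
             rng: np.random.Generator | None = None,
             layer: SEBlock | None = None, training: bool = False) -> Tensor:
    if layer is None:
        c = fm.data.shape[-1] if isinstance(fm, Tensor) else fm.shape[-1]
        layer = SEBlock(c, ratio_hidden, rng or np.random.default_rng(0), "se")
    t = fm if isinstance(fm, Tensor) else Tensor(fm)
    return layer(t, training)
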