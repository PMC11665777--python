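"""Decoder-block contracts: channel reduction, the asymmetric-convolution
oracle, squeeze-excitation behaviour, stage bookkeeping and the head."""

import numpy as np
import pytest

import plutonet as p
from plutonet import nn
from plutonet.decoder import (ACB, PlainBlock, ReductionConv, SEBlock)
from plutonet.encoder import ConfigurationError
from plutonet.nn import BatchNorm, Conv2d, Tensor

RNG = np.random.default_rng(7)


# -- channel reduction -------------------------------------------------------

@pytest.mark.parametrize("shape,filters", [((2, 28, 28, 40), 64),
                                           ((1, 7, 7, 320), 64),
                                           ((3, 14, 14, 112), 32)])
def test_reduce_channels_shape_contract(shape, filters):
    x = RNG.random(shape).astype(np.float32)
    y = p.reduce_channels(x, filters, rng=RNG)
    assert y.data.shape == shape[:3] + (filters,)


def test_reduce_channels_parameter_cost_matches_tensor_walk():
    for cin in (40, 112, 192):
        layer = ReductionConv(cin, 64, RNG, "r")
        analytic = 3 * 3 * cin * 64 + 2 * 64          # conv + full BN
        assert layer.param_count() == analytic
        assert sum(q.data.size for q in layer.params()) == analytic
    acb_layer = ReductionConv(40, 64, RNG, "r", use_acb=True)
    assert acb_layer.param_count() == (9 + 3 + 3) * 40 * 64 + 3 * 2 * 64


def test_reduce_channels_rejects_nonpositive_filters():
    with pytest.raises(ConfigurationError):
        ReductionConv(40, 0, RNG, "r")


# -- asymmetric convolution block -------------------------------------------

def test_acb_with_zeroed_asymmetric_branches_equals_plain_conv_bn_relu():
    """Brute-force equality oracle: copy the 3x3 kernel into a plain
    conv-BN-relu block and zero the 3x1/1x3 branches; outputs must agree."""
    cin, cout = 6, 5
    block = ACB(cin, cout, RNG, "acb")
    block.c31.weight.data[:] = 0.0
    block.c13.weight.data[:] = 0.0
    block.b31.beta.data[:] = 0.0
    block.b13.beta.data[:] = 0.0

    plain = PlainBlock(cin, cout, RNG, "plain")
    plain.conv.weight.data = block.c33.weight.data.copy()
    plain.bn.beta.data = block.b33.beta.data.copy()
    plain.bn.running_mean = block.b33.running_mean.copy()
    plain.bn.running_var = block.b33.running_var.copy()

    x = Tensor(RNG.normal(0, 1, (2, 9, 9, cin)).astype(np.float32))
    ya = block(x, training=False)
    yp = plain(x, training=False)
    assert np.abs(ya.data - yp.data).max() < 1e-5


def test_acb_output_nonnegative_and_shape_preserving():
    x = RNG.normal(0, 1, (2, 14, 14, 64)).astype(np.float32)
    y = p.acb(x, rng=RNG)
    assert y.data.shape == x.shape
    assert (y.data >= 0).all()


# -- squeeze and excitation --------------------------------------------------

def test_se_unit_gate_is_identity_and_zero_gate_annihilates():
    se = SEBlock(8, 3, RNG, "se")
    x = Tensor(RNG.normal(0, 1, (2, 5, 5, 8)).astype(np.float32))

    se.excitation = lambda t: Tensor(np.ones((2, 8), np.float32))
    assert np.array_equal(se(x).data, x.data)

    se.excitation = lambda t: Tensor(np.zeros((2, 8), np.float32))
    assert np.array_equal(se(x).data, np.zeros_like(x.data))


def test_se_gate_never_amplifies():
    x = RNG.normal(0, 1, (2, 6, 6, 16)).astype(np.float32)
    y = p.se_block(x, ratio_hidden=4, rng=RNG)
    assert (np.abs(y.data) <= np.abs(x) + 1e-6).all()


def test_se_rejects_bad_bottleneck():
    with pytest.raises(ConfigurationError):
        SEBlock(16, 0, RNG, "se")


# -- full decoder over a pyramid --------------------------------------------

def _pyramid(size=64, batch=2, seed=0):
    enc = p.build_encoder(p.EncoderConfig(input_size=size))
    x = np.random.default_rng(seed).random((batch, size, size, 3)).astype(np.float32)
    return enc, p.extract_features(enc, x)


def test_stage_outputs_have_reduction_filter_channels(tiny_model):
    size = tiny_model.encoder_config.input_size
    x = RNG.random((2, size, size, 3)).astype(np.float32)
    pyr = tiny_model.encoder(Tensor(x))
    dec = tiny_model.decoder
    e3r = dec.r3(pyr.e3.data)
    e4r = dec.r4(pyr.e4.data)
    e5r = dec.r5a(pyr.e5.data)
    s1 = size // dec.config.stage_strides[0]
    cat = nn.concat([nn.resize_bilinear(e3r, (s1, s1)),
                     nn.resize_bilinear(e4r, (s1, s1)),
                     nn.resize_bilinear(e5r, (s1, s1))])
    assert cat.data.shape[-1] == 3 * 64
    d1 = dec.stage1(cat)
    assert d1.data.shape == (2, s1, s1, 64)


def test_e5_feeds_all_three_decoder_stages():
    """Perturbing only e5 must change every stage's output (e5 is wired into
    d1, d2 and d3), while e1/e2-level features cannot even be passed in."""
    model = p.PlutoNet(p.EncoderConfig(input_size=64), seed=5, with_aux=False)
    x = RNG.random((1, 64, 64, 3)).astype(np.float32)
    pyr = model.encoder(Tensor(x))
    base = model.decoder(pyr, 64).data
    bumped = p.FeaturePyramid(pyr.e3, pyr.e4,
                              p.FeatureMap(Tensor(pyr.e5.data.data + 0.5), 32))
    out = model.decoder(bumped, 64).data
    assert not np.allclose(base, out)


def test_no_skip_connections_from_shallow_encoder_layers():
    """Graph audit: no decoder convolution consumes an e1/e2-width feature
    (EfficientNetB0 shallow stages have 16 or 24 channels)."""
    model = p.PlutoNet(seed=0)
    widths = {m.cin for m in model.decoder.submodules() if isinstance(m, Conv2d)}
    assert widths & {16, 24} == set()


def test_main_branch_forward_is_deterministic(tiny_model):
    size = tiny_model.encoder_config.input_size
    x = RNG.random((1, size, size, 3)).astype(np.float32)
    a = tiny_model.predict(x)
    b = tiny_model.predict(x)
    assert np.array_equal(a, b)


def test_head_range_and_resolution(tiny_model):
    size = tiny_model.encoder_config.input_size
    x = RNG.random((2, size, size, 3)).astype(np.float32)
    pm = tiny_model.predict(x)
    assert pm.shape == (2, size, size, 1)
    assert (pm > 0).all() and (pm < 1).all()


def test_zero_logits_give_uniform_half_map(tiny_model):
    head = tiny_model.decoder.head
    keep_w, keep_b = head.out.weight.data.copy(), head.out.bias.data.copy()
    head.out.weight.data[:] = 0.0
    head.out.bias.data[:] = 0.0
    try:
        size = tiny_model.encoder_config.input_size
        pm = tiny_model.predict(RNG.random((1, size, size, 3)).astype(np.float32))
        assert np.allclose(pm, 0.5)
    finally:
        head.out.weight.data = keep_w
        head.out.bias.data = keep_b


def test_stage_strides_must_decrease():
    with pytest.raises(ConfigurationError):
        p.DecoderConfig(stage_strides=(8, 8, 4)).validate()
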