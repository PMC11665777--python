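"""Truncated-backbone contracts: tap geometry, determinism, truncation
exactness, and the analytic per-layer parameter oracle."""

import numpy as np
import pytest

import plutonet as p
from plutonet.encoder import _B0_STAGES, ConfigurationError


def _analytic_backbone_params(truncate_after=(6, 1)):
    """Independent oracle: closed-form conv/BN/SE parameter formulas summed
    over every instantiated layer of the trunk."""
    total = 3 * 3 * 3 * 32 + 2 * 32          # stem conv + BN
    for si, (e, k, s, cin, cout, r) in enumerate(_B0_STAGES, start=1):
        for bi in range(1, r + 1):
            ci = cin if bi == 1 else cout
            mid = ci * e
            if e != 1:
                total += ci * mid + 2 * mid   # expand conv + BN
            total += k * k * mid + 2 * mid    # depthwise + BN
            se = max(1, int(ci * 0.25))
            total += mid * se + se + se * mid + mid   # SE (biased denses)
            total += mid * cout + 2 * cout    # project + BN
            if (si, bi) == truncate_after:
                return total
    raise AssertionError("truncation point not reached")


@pytest.mark.parametrize("size,expected", [(224, (28, 14, 7)), (96, (12, 6, 3))])
def test_tap_spatial_sizes_follow_stride_arithmetic(size, expected):
    enc = p.build_encoder(p.EncoderConfig(input_size=size))
    x = np.zeros((2, size, size, 3), dtype=np.float32)
    pyr = p.extract_features(enc, x)
    for fm, stride, side in zip(pyr, (8, 16, 32), expected):
        assert fm.stride == stride
        assert fm.data.data.shape[0] == 2
        assert fm.data.data.shape[1:3] == (side, side)
        assert np.isfinite(fm.data.data).all()


def test_tap_channels_and_batch_preserved():
    enc = p.build_encoder(p.EncoderConfig(input_size=64))
    assert enc.tap_channels == (40, 112, 192)
    pyr = p.extract_features(enc, np.zeros((3, 64, 64, 3), np.float32))
    assert all(fm.data.data.shape[0] == 3 for fm in pyr)


def test_identical_inputs_give_bitwise_identical_pyramids():
    enc = p.build_encoder(p.EncoderConfig(input_size=64))
    x = np.random.default_rng(0).random((1, 64, 64, 3)).astype(np.float32)
    a = p.extract_features(enc, x)
    b = p.extract_features(enc, x)
    for fa, fb in zip(a, b):
        assert np.array_equal(fa.data.data, fb.data.data)


def test_configuration_errors():
    with pytest.raises(ConfigurationError):
        p.build_encoder(p.EncoderConfig(input_size=100))
    with pytest.raises(ConfigurationError):
        p.build_encoder(p.EncoderConfig(
            tap_stages=((5, 3), (3, 2), (6, 1))))     # wrong order
    with pytest.raises(ConfigurationError):
        p.build_encoder(p.EncoderConfig(truncate_after=(6, 2)))  # beyond e5


def test_nothing_is_instantiated_beyond_the_e5_tap():
    enc = p.build_encoder()
    assert enc._block_pos[-1] == (6, 1)
    # stage 7 and the 1x1 expansion/classifier never exist
    assert all(si <= 6 for si, _ in enc._block_pos)


def test_trunk_parameters_match_analytic_per_layer_oracle():
    enc = p.build_encoder()
    assert enc.param_count() == _analytic_backbone_params() == 1_114_300


def test_wrong_spatial_size_raises():
    enc = p.build_encoder(p.EncoderConfig(input_size=64))
    with pytest.raises(ValueError):
        p.extract_features(enc, np.zeros((1, 96, 96, 3), np.float32))
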