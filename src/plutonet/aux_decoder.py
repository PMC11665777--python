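"""Training-only auxiliary decoder built on element-wise tap products.

The auxiliary branch reuses the main decoder's 64-channel reduced taps
(shared weights, so channel alignment costs nothing), aligns them to the
finest tap scale, forms the attention-style products e3*e4*e5 and e4*e5,
concatenates them with e5, and maps the 192 channels to a single logit:

    1x1 conv 192->1 (no bias)  ->  3x1 conv 1->1 (+bias)
                               ->  1x3 conv 1->1 (+bias)  ->  sigmoid

The head owns exactly 192 + 4 + 4 = 200 trainable parameters — the entire
cost of the branch — and is detached at inference time: the main prediction
is bitwise identical with or without it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .decoder import ModifiedPartialDecoder
from .encoder import FeaturePyramid
from .nn import Conv2d, Module, Tensor


@dataclass(frozen=True)
class AuxConfig:
    align_channels: int = 64     # channels of the shared reduced taps


class AuxiliaryDecoder(Module):
    def __init__(self, decoder: ModifiedPartialDecoder,
                 rng: np.random.Generator, config: AuxConfig = AuxConfig()):
        self.config = config
        self._decoder = [decoder]   # list: keep out of param discovery
        c = 3 * config.align_channels
        self.fuse = Conv2d(c, 1, 1, bias=False, rng=rng, name="aux_fuse")
        self.refine_v = Conv2d(1, 1, (3, 1), bias=True, rng=rng, name="aux_rv")
        self.refine_h = Conv2d(1, 1, (1, 3), bias=True, rng=rng, name="aux_rh")
        self.name = "aux"

    def __call__(self, pyramid: FeaturePyramid, input_size: int,
                 training: bool = False) -> Tensor:
        dec = self._decoder[0]
        e3r, e4r, e5r = dec.reduced_taps(pyramid, training)
        size = pyramid.e3.data.data.shape[1]
        e4r = nn.resize_bilinear(e4r, (size, size))
        e5r = nn.resize_bilinear(e5r, (size, size))
        p345 = e3r * e4r * e5r
        p45 = e4r * e5r
        h = nn.concat([p345, p45, e5r])
        h = self.refine_h(self.refine_v(self.fuse(h)))
        h = nn.sigmoid(h)
        return nn.resize_bilinear(h, (input_size, input_size))


def aux_decode(decoder: ModifiedPartialDecoder, pyramid: FeaturePyramid,
               input_size: int, rng: np.random.Generator | None = None,
               layer: AuxiliaryDecoder | None = None,
               training: bool = False) -> Tensor:
    """Run the auxiliary decoder over an encoder pyramid (Pa in [0,1])."""
    if layer is None:
        layer = AuxiliaryDecoder(decoder, rng or np.random.default_rng(0))
    return layer(pyramid, input_size, training)


def count_aux_parameters(model_with_aux, model_without_aux) -> int:
    """Trainable-parameter difference attributable to the auxiliary branch."""
    cw, co = model_with_aux.config_fingerprint(), model_without_aux.config_fingerprint()
    if cw != co:
        raise ValueError(f"base configurations differ: {cw} vs {co}")
    return model_with_aux.count_parameters(True) - model_without_aux.count_parameters(True)
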