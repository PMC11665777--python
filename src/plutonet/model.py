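"""Assembly of the full segmentation network and its ablation variants."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .aux_decoder import AuxiliaryDecoder
from .decoder import DecoderConfig, ModifiedPartialDecoder
from .encoder import Encoder, EncoderConfig, FeaturePyramid
from .nn import Module, Tensor

#: ablation ladder: trunk + partial decoder with plain blocks (AS1),
#: + asymmetric convolution blocks (AS2), + squeeze-excitation (AS3),
#: + auxiliary decoder (full)
VARIANTS = ("AS1", "AS2", "AS3", "full")


class PlutoNet(Module):
    def __init__(self, encoder_config: EncoderConfig | None = None,
                 decoder_config: DecoderConfig | None = None,
                 with_aux: bool = True, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.encoder_config = encoder_config or EncoderConfig()
        self.decoder_config = decoder_config or DecoderConfig()
        self.encoder = Encoder(self.encoder_config, rng)
        self.decoder = ModifiedPartialDecoder(self.encoder.tap_channels,
                                              self.decoder_config, rng)
        self.aux = AuxiliaryDecoder(self.decoder, rng) if with_aux else None

    # -- forward -----------------------------------------------------------
    def forward(self, images, training: bool = False,
                with_aux: bool | None = None):
        """Return (Pm, Pa); Pa is None when the auxiliary branch is off."""
        t = images if isinstance(images, Tensor) else Tensor(images)
        pyramid = self.encoder(t, training)
        size = self.encoder_config.input_size
        pm = self.decoder(pyramid, size, training)
        use_aux = self.aux is not None if with_aux is None else with_aux
        pa = self.aux(pyramid, size, training) if (use_aux and self.aux) else None
        return pm, pa

    def predict(self, images) -> np.ndarray:
        """Inference: main-branch probabilities only, in [0,1]."""
        pm, _ = self.forward(images, training=False, with_aux=False)
        return pm.data

    # -- bookkeeping --------------------------------------------------------
    def trainable_parameters(self, include_aux: bool = True):
        ps = self.encoder.params() + self.decoder.params()
        if include_aux and self.aux is not None:
            ps += self.aux.params()
        return ps

    def count_parameters(self, include_aux: bool = True) -> int:
        return int(sum(p.data.size for p in self.trainable_parameters(include_aux)))

    def config_fingerprint(self) -> tuple:
        return (self.encoder_config, self.decoder_config)

    def save_weights(self, path: str, include_aux: bool = False) -> None:
        ps = self.trainable_parameters(include_aux)
        np.savez(path, n=np.int64(len(ps)),
                 **{f"p{i}": p.data for i, p in enumerate(ps)})

    def load_weights(self, path: str, include_aux: bool = False) -> None:
        blob = np.load(path)
        ps = self.trainable_parameters(include_aux)
        if int(blob["n"]) != len(ps):
            raise ValueError("weight archive does not match this configuration")
        for i, p in enumerate(ps):
            p.data = blob[f"p{i}"].astype(np.float32)


def build_variant(variant: str, input_size: int = 224, seed: int = 0) -> PlutoNet:
    """Build one rung of the ablation ladder.

    AS1: plain convolution blocks, no squeeze-excitation, no auxiliary head.
    AS2: asymmetric convolution blocks.  AS3: + squeeze-excitation.
    full: + the 200-parameter auxiliary decoder.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; pick from {VARIANTS}")
    enc = EncoderConfig(input_size=input_size)
    dec = DecoderConfig(use_acb=variant != "AS1", use_se=variant in ("AS3", "full"))
    return PlutoNet(enc, dec, with_aux=variant == "full", seed=seed)
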